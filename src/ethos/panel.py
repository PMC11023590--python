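"""Long-format country-year panel container and CSV round-trip.

A panel holds one row per (country, year) with named real-valued variables:
life satisfaction (``LS``, 0-10 ladder), healthy life expectancy at birth
(``HLEB``, years), per-capita GDP, the Gini index, religion population
shares, gross enrolment rates and per-student expenditures for the three
education levels, and per-capita education/health expenditures.  The
container is a thin, validated wrapper over a :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

COUNTRY = "country"
YEAR = "year"

#: Canonical variable dictionary (name -> short description / units).
VARIABLE_DICTIONARY = {
    "LS": "life satisfaction, 0-10 ladder",
    "HLEB": "healthy life expectancy at birth, years",
    "LEB": "life expectancy at birth, years",
    "GDP": "GDP per capita, $ PPP",
    "LNGDP": "natural log of GDP per capita",
    "GINI": "Gini index",
    "BUDP": "Buddhist population share, [0,1]",
    "CHRP": "Christian population share, [0,1]",
    "HINP": "Hindu population share, [0,1]",
    "ISLP": "Muslim population share, [0,1]",
    "JUDP": "Jewish population share, [0,1]",
    "BUDM": "Buddhist majority dummy",
    "CHRM": "Christian majority dummy",
    "HINM": "Hindu majority dummy",
    "ISLM": "Muslim majority dummy",
    "JUDM": "Jewish majority dummy",
    "GEP": "gross enrolment, primary, percent",
    "GES": "gross enrolment, secondary, percent",
    "GET": "gross enrolment, tertiary, percent",
    "EEP": "education expenditure per student, primary, thousand $ PPP",
    "EES": "education expenditure per student, secondary, thousand $ PPP",
    "EET": "education expenditure per student, tertiary, thousand $ PPP",
    "EE": "government education expenditure per capita, $ PPP",
    "HE": "total health expenditure per capita, $ PPP",
}

RELIGION_SHARES = ["BUDP", "CHRP", "HINP", "ISLP", "JUDP"]
RELIGION_DUMMIES = ["BUDM", "CHRM", "HINM", "ISLM", "JUDM"]
ENROLMENT_VARS = ["GEP", "GES", "GET"]
EXPENDITURE_VARS = ["EEP", "EES", "EET"]


class PanelError(ValueError):
    """Raised for malformed panel data (duplicates, bad types, bad ranges)."""


@dataclass
class PanelDataset:
    """Balanced or gappy long-format country-year panel.

    Parameters
    ----------
    df
        Long-format frame with ``country`` and ``year`` columns plus any
        number of numeric variable columns.
    metadata
        Free-form provenance notes, reports from processing steps, etc.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        missing = [c for c in (COUNTRY, YEAR) if c not in self.df.columns]
        if missing:
            raise PanelError(f"panel is missing required column(s): {missing}")
        dup = self.df.duplicated([COUNTRY, YEAR])
        if dup.any():
            offenders = (
                self.df.loc[dup, [COUNTRY, YEAR]]
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            raise PanelError(
                "duplicate (country, year) pairs: " + ", ".join(map(str, offenders))
            )
        for col in self.variables:
            if not pd.api.types.is_numeric_dtype(self.df[col]):
                coerced = pd.to_numeric(self.df[col], errors="coerce")
                bad = coerced.isna() & self.df[col].notna()
                if bad.any():
                    rows = self.df.index[bad].tolist()[:5]
                    raise PanelError(
                        f"non-numeric values in column {col!r} at rows {rows}"
                    )
                self.df[col] = coerced

    @property
    def variables(self) -> list[str]:
        return [c for c in self.df.columns if c not in (COUNTRY, YEAR)]

    @property
    def countries(self) -> list[str]:
        return sorted(self.df[COUNTRY].unique().tolist())

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self.df[YEAR].unique())

    @property
    def n_obs(self) -> int:
        return len(self.df)

    def is_balanced(self) -> bool:
        counts = self.df.groupby(COUNTRY)[YEAR].agg(["size", "nunique"])
        year_sets = self.df.groupby(COUNTRY)[YEAR].apply(frozenset)
        return counts["size"].nunique() <= 1 and year_sets.nunique() <= 1

    def subset_countries(self, keep: Iterable[str]) -> "PanelDataset":
        keep = set(keep)
        return PanelDataset(
            self.df[self.df[COUNTRY].isin(keep)].copy(), dict(self.metadata)
        )

    def copy(self) -> "PanelDataset":
        return PanelDataset(self.df.copy(), dict(self.metadata))


def read_panel(path: str | Path) -> PanelDataset:
    """Read a long-format CSV panel; validates keys and numeric columns."""
    df = pd.read_csv(path)
    if COUNTRY not in df.columns or YEAR not in df.columns:
        raise PanelError(
            f"{path}: CSV must contain '{COUNTRY}' and '{YEAR}' columns; "
            f"found {list(df.columns)}"
        )
    df[YEAR] = df[YEAR].astype(int)
    df[COUNTRY] = df[COUNTRY].astype(str)
    return PanelDataset(df, metadata={"source": str(path)})


def write_panel(panel: PanelDataset, path: str | Path) -> None:
    """Write a panel to CSV, values at 12 significant digits (lossless round trip)."""
    out = panel.df.sort_values([COUNTRY, YEAR])
    out.to_csv(path, index=False, float_format="%.12g")
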