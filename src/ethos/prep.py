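"""Panel preprocessing: interpolation, lagged means, dummies, balancing.

These are the standard construction steps for the happiness-health system:
per-country linear interpolation of interior gaps, the k-year trailing mean
of life satisfaction (``LSk``) used as the lagged regressor of the health
equation, strict-majority religion dummies, the log-GDP transform, and
enforcement of a balanced estimation sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import COUNTRY, YEAR, PanelDataset, PanelError


def _complete_year_grid(df: pd.DataFrame) -> pd.DataFrame:
    """Reindex each country to its full consecutive year range.

    A missing year row is treated as a row of missing values, so interior
    whole-year gaps are interpolatable like any other gap.
    """
    spans = df.groupby(COUNTRY)[YEAR].agg(["min", "max", "size"])
    if (spans["size"] == spans["max"] - spans["min"] + 1).all():
        return df.sort_values([COUNTRY, YEAR]).reset_index(drop=True)
    pieces = []
    for country, g in df.groupby(COUNTRY, sort=True):
        years = np.arange(g[YEAR].min(), g[YEAR].max() + 1)
        g = g.set_index(YEAR).reindex(years)
        g[COUNTRY] = country
        g.index.name = YEAR
        pieces.append(g.reset_index())
    out = pd.concat(pieces, ignore_index=True)
    return out[[COUNTRY, YEAR] + [c for c in df.columns if c not in (COUNTRY, YEAR)]]


def interpolate_missing(
    panel: PanelDataset, variables: list[str] | None = None
) -> PanelDataset:
    """Fill interior gaps per (country, variable) by straight lines in year.

    Leading and trailing gaps are never extrapolated; they are counted in the
    report instead.  Observed values are never modified, so the operation is
    idempotent.  The report (``metadata['interpolation_report']``) lists the
    number of cells filled, the cells left unfilled, and the countries that
    remain incomplete.
    """
    variables = variables or panel.variables
    df = _complete_year_grid(panel.df)
    filled = 0
    for var in variables:
        if not df[var].isna().any():
            continue
        for _, g in df.groupby(COUNTRY, sort=False):
            s = g[var]
            if s.notna().sum() < 2:
                continue
            interp = s.set_axis(g[YEAR]).interpolate(
                method="index", limit_area="inside"
            )
            newly = interp.notna().to_numpy() & s.isna().to_numpy()
            if newly.any():
                df.loc[g.index[newly], var] = interp.to_numpy()[newly]
                filled += int(newly.sum())
    remaining = df[variables].isna().sum().to_dict()
    incomplete = sorted(
        df.loc[df[variables].isna().any(axis=1), COUNTRY].unique().tolist()
    )
    meta = dict(panel.metadata)
    meta["interpolation_report"] = {
        "cells_filled": filled,
        "cells_unfilled_by_variable": {k: int(v) for k, v in remaining.items() if v},
        "incomplete_countries": incomplete,
    }
    return PanelDataset(df, meta)


def compute_lagged_mean(panel: PanelDataset, variable: str, k: int) -> PanelDataset:
    """Add ``<variable>k<k>``: the mean of the variable over years t-1 ... t-k.

    The current year is excluded.  The value is missing whenever any of the k
    previous years is missing (in particular for each country's first k years).
    """
    if k < 1:
        raise ValueError(f"lag depth k must be >= 1, got {k}")
    if variable not in panel.df.columns:
        raise PanelError(f"variable {variable!r} not in panel")
    df = panel.df.sort_values([COUNTRY, YEAR]).reset_index(drop=True)
    lagged = (
        df.groupby(COUNTRY, sort=False)[variable]
        .transform(lambda s: s.shift(1).rolling(k, min_periods=k).mean())
    )
    df[f"{variable}k{k}"] = lagged
    return PanelDataset(df, dict(panel.metadata))


def derive_majority_dummies(
    panel: PanelDataset, share_vars: list[str], threshold: float = 0.5
) -> PanelDataset:
    """Add ``<X>M`` = 1 where the population share ``<X>P`` strictly exceeds threshold.

    "Majority" is strict (share > threshold, default 0.5); a share exactly at
    the threshold is not a majority.
    """
    df = panel.df.copy()
    for var in share_vars:
        if var not in df.columns:
            raise PanelError(f"share variable {var!r} not in panel")
        s = df[var]
        bad = s.notna() & ((s < 0) | (s > 1))
        if bad.any():
            raise PanelError(
                f"share variable {var!r} outside [0,1] at rows {df.index[bad].tolist()[:5]}"
            )
        name = var[:-1] + "M" if var.endswith("P") else var + "_MAJ"
        df[name] = np.where(s.isna(), np.nan, (s > threshold).astype(float))
    return PanelDataset(df, dict(panel.metadata))


def log_transform(panel: PanelDataset, variable: str) -> PanelDataset:
    """Add ``LN<variable>`` = natural log; errors on non-positive values."""
    df = panel.df.copy()
    s = df[variable]
    bad = s.notna() & (s <= 0)
    if bad.any():
        raise PanelError(
            f"log transform of {variable!r}: non-positive values at rows "
            f"{df.index[bad].tolist()[:5]}"
        )
    df[f"LN{variable}"] = np.log(s)
    return PanelDataset(df, dict(panel.metadata))


def enforce_balance(
    panel: PanelDataset,
    year_range: tuple[int, int],
    variables: list[str] | None = None,
) -> PanelDataset:
    """Keep only countries fully observed over ``year_range`` for ``variables``.

    Dropped countries are listed in ``metadata['balance_report']``.  Raises if
    no country survives.
    """
    lo, hi = year_range
    variables = variables or panel.variables
    df = panel.df[(panel.df[YEAR] >= lo) & (panel.df[YEAR] <= hi)]
    n_years = hi - lo + 1
    keep, dropped = [], []
    for country, g in df.groupby(COUNTRY, sort=True):
        complete = len(g) == n_years and g[variables].notna().all().all()
        (keep if complete else dropped).append(country)
    if not keep:
        raise PanelError(
            f"no country is fully observed on {variables} over {lo}-{hi}"
        )
    out = df[df[COUNTRY].isin(keep)].copy()
    meta = dict(panel.metadata)
    meta["balance_report"] = {
        "year_range": [lo, hi],
        "n_retained": len(keep),
        "dropped_countries": dropped,
    }
    return PanelDataset(out, meta)
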