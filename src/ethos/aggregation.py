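"""Post-estimation arithmetic over coefficient tables.

Works on the four printed context tables (religion coded as majority
dummies or population shares, education as gross enrolment or per-student
expenditure) or on freshly estimated ones: significance filtering, average
religion/education links, sign matrices of significant links,
cross-context coefficient differences, and cumulative education-level
gains (coefficient times sample mean, cumulated primary -> secondary ->
tertiary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

RELIGION_ROOTS = ["BUD", "CHR", "HIN", "ISL", "JUD"]
EDUCATION_LEVELS = ["P", "S", "T"]

#: Context labels of the four shipped tables.
TABLE_CONTEXTS = {
    "T3": {"religion": "majority", "education": "enrolment"},
    "T4": {"religion": "percentage", "education": "expenditure"},
    "T5": {"religion": "percentage", "education": "enrolment"},
    "T6": {"religion": "majority", "education": "expenditure"},
}

#: Reported goodness of fit for the shipped tables (LS eq, health eq).
TABLE_R2 = {"T3": (0.60, 0.73), "T4": (0.60, 0.72),
            "T5": (0.61, 0.72), "T6": (0.61, 0.72)}


def canonical_root(variable: str) -> str:
    """Map a context-specific name to its cross-context root.

    ``CHRM``/``CHRP`` -> ``CHR``; ``GEP``/``EEP`` -> ``EDUP``; everything
    else maps to itself (``LNGDP``, ``GINI``, ``HLEB``, ``LSk4``, ``CONS``).
    """
    if len(variable) == 4 and variable[:3] in RELIGION_ROOTS and variable[3] in "MP":
        return variable[:3]
    if variable[:2] in ("GE", "EE") and len(variable) == 3 and variable[2] in "PST":
        return "EDU" + variable[2]
    return variable


@dataclass
class CoefficientTable:
    """Named coefficients with p-values for one equation of one context."""

    table_id: str
    equation: str  # "LS" or "HLEB"/"LEB"
    entries: pd.DataFrame  # columns: variable, estimate, p_value (+ extras)
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"variable", "estimate", "p_value"}
        if not required <= set(self.entries.columns):
            raise ValueError(f"entries must have columns {sorted(required)}")
        p = self.entries["p_value"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")

    def estimate(self, variable: str) -> float:
        row = self.entries[self.entries["variable"] == variable]
        if row.empty:
            raise KeyError(f"{variable!r} not in table {self.table_id}/{self.equation}")
        return float(row["estimate"].iloc[0])

    def group_variables(self, group: str) -> list[str]:
        names = self.entries["variable"]
        if group == "REL":
            sel = names.str[:3].isin(RELIGION_ROOTS) & names.str.len().eq(4)
        elif group == "EDU":
            sel = names.str[:2].isin(["GE", "EE"]) & names.str.len().eq(3)
        else:
            raise ValueError(f"group must be 'REL' or 'EDU', got {group!r}")
        return names[sel].tolist()


@dataclass
class SummaryStats:
    """Per-variable sample summary (mean, SD, max, min, median)."""

    table: pd.DataFrame  # indexed by variable

    def mean(self, variable: str) -> float:
        if variable not in self.table.index:
            raise KeyError(f"no summary mean for {variable!r}")
        return float(self.table.loc[variable, "mean"])

    def check_ordering(self) -> list[str]:
        """Variables whose printed min/mean/median/max ordering is inconsistent."""
        bad = []
        for var, row in self.table.iterrows():
            lo, hi, mean = row["min"], row["max"], row["mean"]
            med = row.get("median", np.nan)
            if not (lo <= mean <= hi) or (np.isfinite(med) and not (lo <= med <= hi)):
                bad.append(var)
        return bad


# ---------------------------------------------------------------------------
# fixture loading


def _fixture_path() -> Path:
    return Path(resources.files("ethos") / "fixtures")


def load_summary_stats(path: str | Path | None = None) -> SummaryStats:
    path = Path(path) if path else _fixture_path() / "table2_stats.csv"
    df = pd.read_csv(path).set_index("variable")
    return SummaryStats(df)


def load_coefficient_table(
    table_id: str, equation: str, directory: str | Path | None = None
) -> CoefficientTable:
    """Load one shipped printed table, e.g. ``('T3', 'HLEB')``."""
    directory = Path(directory) if directory else _fixture_path()
    number = table_id.lstrip("T")
    path = directory / f"table{number}_{equation.lower()}.csv"
    df = pd.read_csv(path)
    return CoefficientTable(
        table_id=table_id, equation=equation, entries=df,
        context=dict(TABLE_CONTEXTS.get(table_id, {})),
    )


def load_all_tables(directory: str | Path | None = None) -> dict[tuple[str, str], CoefficientTable]:
    return {
        (tid, eq): load_coefficient_table(tid, eq, directory)
        for tid in TABLE_CONTEXTS
        for eq in ("LS", "HLEB")
    }


# ---------------------------------------------------------------------------
# operations


def filter_significant(table: CoefficientTable, alpha: float) -> CoefficientTable:
    """Keep entries with p < alpha.  Monotone in alpha."""
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    kept = table.entries[table.entries["p_value"] < alpha].reset_index(drop=True)
    return CoefficientTable(table.table_id, table.equation, kept, dict(table.context))


def mean_significant_links(
    table: CoefficientTable, group: str, alpha: float = 0.10
) -> float:
    """Mean of the significant (p < alpha) coefficients of a variable group.

    Returns NaN when no group coefficient is significant.
    """
    names = table.group_variables(group)
    sub = table.entries[
        table.entries["variable"].isin(names) & (table.entries["p_value"] < alpha)
    ]
    if sub.empty:
        return float("nan")
    return float(sub["estimate"].mean())


def link_sign_matrix(
    tables: dict[tuple[str, str], CoefficientTable], alpha: float = 0.10
) -> pd.DataFrame:
    """Sign of each significant link across every (table, equation) context.

    Cell values: ``'+'`` / ``'-'`` for significant positive/negative
    coefficients, ``'0'`` otherwise.  Rows are canonical variable roots,
    columns (table_id, equation) pairs.
    """
    records = {}
    for (tid, eq), table in tables.items():
        col = {}
        for _, row in table.entries.iterrows():
            sign = "0"
            if row["p_value"] < alpha:
                sign = "+" if row["estimate"] > 0 else "-"
            col[canonical_root(row["variable"])] = sign
        records[(tid, eq)] = col
    out = pd.DataFrame(records)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["table", "equation"])
    return out


def cross_table_differences(
    table_a: CoefficientTable,
    table_b: CoefficientTable,
    policy: str = "raw",
    alpha: float = 0.10,
    align: str = "strict",
) -> pd.DataFrame:
    """Per-variable coefficient differences A - B under a significance policy.

    Policies:
      ``raw``                A - B on the printed estimates, always.
      ``zero_ns``            replace non-significant estimates by 0, then subtract.
      ``null_if_either_ns``  report 0 when either entry is non-significant.

    All three exist because the published difference table mixes the rules;
    no single policy reproduces every printed cell.  Variables are aligned
    across contexts by their canonical roots (e.g. ``CHRM`` vs ``CHRP``).
    """
    if policy not in ("raw", "zero_ns", "null_if_either_ns"):
        raise ValueError(f"unknown policy {policy!r}")

    def rooted(t: CoefficientTable) -> pd.DataFrame:
        df = t.entries.copy()
        df["root"] = df["variable"].map(canonical_root)
        return df.set_index("root")

    a, b = rooted(table_a), rooted(table_b)
    if set(a.index) != set(b.index):
        if align != "intersection":
            raise ValueError(
                f"variable sets do not align: {sorted(set(a.index) ^ set(b.index))}"
            )
        common = [r for r in a.index if r in set(b.index)]
        a, b = a.loc[common], b.loc[common]
    rows = []
    for root in a.index:
        ea, pa = a.loc[root, "estimate"], a.loc[root, "p_value"]
        eb, pb = b.loc[root, "estimate"], b.loc[root, "p_value"]
        sig_a, sig_b = pa < alpha, pb < alpha
        if policy == "raw":
            diff = ea - eb
        elif policy == "zero_ns":
            diff = (ea if sig_a else 0.0) - (eb if sig_b else 0.0)
        else:
            diff = ea - eb if (sig_a and sig_b) else 0.0
        rows.append({"variable": root, "difference": diff,
                     "estimate_a": ea, "estimate_b": eb,
                     "significant_a": bool(sig_a), "significant_b": bool(sig_b)})
    return pd.DataFrame(rows)


def education_level_sums(
    social_table: CoefficientTable,
    individual_table: CoefficientTable,
    stats: SummaryStats,
) -> pd.DataFrame:
    """Cumulative education-level contributions, coefficient x sample mean.

    For each level L in primary/secondary/tertiary the contribution is
    ``coef(GE_L) * mean(GE_L) + coef(EE_L) * mean(EE_L)``, taking the
    enrolment coefficient from the social-context table and the per-student
    expenditure coefficient from the individual-context table, *regardless
    of significance* (expenditure means are in thousand $ PPP).  The output
    cumulates primary -> secondary -> tertiary.
    """
    rows = []
    cumulative = 0.0
    for level in EDUCATION_LEVELS:
        ge, ee = f"GE{level}", f"EE{level}"
        contribution = (
            social_table.estimate(ge) * stats.mean(ge)
            + individual_table.estimate(ee) * stats.mean(ee)
        )
        cumulative += contribution
        rows.append({"level": level, "contribution": contribution,
                     "cumulative": cumulative})
    return pd.DataFrame(rows)


def coupling_averages(
    tables: dict[tuple[str, str], CoefficientTable],
    health_equation: str = "HLEB",
    lsk_variable: str = "LSk4",
) -> dict[str, float]:
    """Average the health->happiness and lagged-happiness->health couplings.

    The mean of the four printed ``HLEB`` coefficients in the LS equations
    (~0.086) and the mean of the four ``LSk4`` coefficients in the health
    equations (~3.161); these feed the dynamical system.
    """
    eta3 = np.mean(
        [t.estimate(health_equation) for (tid, eq), t in tables.items() if eq == "LS"]
    )
    theta3 = np.mean(
        [t.estimate(lsk_variable) for (tid, eq), t in tables.items()
         if eq == health_equation]
    )
    return {"eta3": float(eta3), "theta3": float(theta3)}


def validate_coefficient_table(
    table: CoefficientTable, z_tol: float = 0.015, ci_tol: float = 5e-4
) -> list[dict]:
    """Internal-consistency check of a printed table at printed precision.

    Verifies z = estimate/std_err (printed to 2 d.p.) and
    CI = estimate +/- 1.96 * std_err (printed to the estimate's precision).
    Returns a list of failing cells; empty means fully consistent.
    """
    failures = []
    for _, row in table.entries.iterrows():
        if {"std_err", "z"} <= set(row.index):
            z = row["estimate"] / row["std_err"]
            if abs(z - row["z"]) > 0.005 + z_tol * abs(z):
                failures.append({"table": table.table_id, "equation": table.equation,
                                 "variable": row["variable"], "check": "z",
                                 "expected": z, "printed": row["z"]})
        if {"std_err", "ci_low", "ci_high"} <= set(row.index):
            lo = row["estimate"] - 1.959964 * row["std_err"]
            hi = row["estimate"] + 1.959964 * row["std_err"]
            scale = max(abs(row["estimate"]), 1.0)
            if abs(lo - row["ci_low"]) > ci_tol * scale * 10 or \
               abs(hi - row["ci_high"]) > ci_tol * scale * 10:
                failures.append({"table": table.table_id, "equation": table.equation,
                                 "variable": row["variable"], "check": "ci",
                                 "expected": (lo, hi),
                                 "printed": (row["ci_low"], row["ci_high"])})
    return failures
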