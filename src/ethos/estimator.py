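"""Two-equation system estimation by 2SLS and 3SLS, from first principles.

The structural system is

    LS_it   = x'_it eta   + eta3 HLEB_it + eps_it
    HLEB_it = w'_it theta + theta3 LSk_it + zeta_it

with ``HLEB`` endogenous in the happiness equation (the disturbances are
cross-correlated and ``HLEB`` carries its own shock) and ``LSk`` -- the
trailing k-year mean of LS -- predetermined, hence usable as an instrument.
2SLS projects each endogenous regressor on the instrument set; 3SLS adds a
single feasible-GLS step over the stacked equations, weighting by the
inverse of the cross-equation residual covariance estimated from the 2SLS
residuals.  Inference is classical with normal (z) critical values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .panel import COUNTRY, PanelDataset

CONST = "const"
Z975 = stats.norm.ppf(0.975)  # 1.959964...


class EstimationError(ValueError):
    """Raised for rank-deficient or under-identified estimation problems."""


@dataclass(frozen=True)
class EquationSpec:
    """One structural equation: dependent, endogenous and exogenous regressors."""

    name: str
    dependent: str
    endogenous_rhs: tuple[str, ...] = ()
    exogenous_rhs: tuple[str, ...] = (CONST,)

    def __post_init__(self) -> None:
        rhs = set(self.endogenous_rhs) | set(self.exogenous_rhs)
        if self.dependent in rhs:
            raise ValueError(f"{self.name}: dependent variable appears on the RHS")
        if set(self.endogenous_rhs) & set(self.exogenous_rhs):
            raise ValueError(f"{self.name}: endogenous and exogenous lists overlap")

    @property
    def regressors(self) -> tuple[str, ...]:
        return tuple(self.endogenous_rhs) + tuple(self.exogenous_rhs)


@dataclass(frozen=True)
class SystemSpec:
    """Ordered equations plus the common instrument set."""

    equations: tuple[EquationSpec, ...]
    instruments: tuple[str, ...]
    fe_mode: str = "pooled"  # "pooled" | "within"

    def __post_init__(self) -> None:
        if self.fe_mode not in ("pooled", "within"):
            raise ValueError(f"fe_mode must be 'pooled' or 'within', got {self.fe_mode!r}")
        dependents = {eq.dependent for eq in self.equations}
        if dependents & set(self.instruments):
            raise ValueError("instruments must exclude contemporaneous dependents")


@dataclass
class CoefficientEstimate:
    variable: str
    estimate: float
    std_err: float

    @property
    def z(self) -> float:
        return self.estimate / self.std_err

    @property
    def p_value(self) -> float:
        return 2 * (1 - stats.norm.cdf(abs(self.z)))

    @property
    def ci_low(self) -> float:
        return self.estimate - Z975 * self.std_err

    @property
    def ci_high(self) -> float:
        return self.estimate + Z975 * self.std_err


@dataclass
class EstimationResult:
    """Per-equation coefficient tables plus system-level metadata."""

    coefficients: dict[str, list[CoefficientEstimate]]
    sigma: np.ndarray
    r2: dict[str, float]
    n_obs: int
    spec: SystemSpec
    method: str
    metadata: dict = field(default_factory=dict)

    def coefficient(self, equation: str, variable: str) -> CoefficientEstimate:
        for c in self.coefficients[equation]:
            if c.variable == variable:
                return c
        raise KeyError(f"{variable!r} not in equation {equation!r}")

    def table(self, equation: str) -> pd.DataFrame:
        rows = [
            {
                "variable": c.variable,
                "estimate": c.estimate,
                "std_err": c.std_err,
                "z": c.z,
                "p_value": c.p_value,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
            }
            for c in self.coefficients[equation]
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design-matrix assembly


def _check_rank(M: np.ndarray, names: list[str], context: str) -> None:
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # identify an offending column by dropping one at a time
        collinear = []
        for j in range(M.shape[1]):
            sub = np.delete(M, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(names[j])
        raise EstimationError(
            f"{context}: design matrix is rank deficient "
            f"(rank {rank} < {M.shape[1]}); collinear columns include {collinear}"
        )


def _matrix(df: pd.DataFrame, names: tuple[str, ...]) -> np.ndarray:
    cols = []
    for name in names:
        if name == CONST:
            cols.append(np.ones(len(df)))
        else:
            cols.append(df[name].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def estimation_frame(panel: PanelDataset, spec: SystemSpec) -> pd.DataFrame:
    """Complete-case frame over every variable any equation or instrument uses."""
    used = set(spec.instruments) - {CONST}
    for eq in spec.equations:
        used |= {eq.dependent, *eq.endogenous_rhs, *eq.exogenous_rhs} - {CONST}
    df = panel.df.dropna(subset=sorted(used))
    return df.reset_index(drop=True)


def within_transform(
    panel: PanelDataset, variables: list[str] | None = None, tol: float = 1e-10
) -> tuple[PanelDataset, list[str]]:
    """Demean each variable by country; returns (panel, zero-within-variance vars).

    Time-invariant regressors (e.g. majority-religion dummies) are
    annihilated by the transformation and must be dropped from any
    within-specification; they are returned for exactly that purpose.
    """
    variables = variables or panel.variables
    df = panel.df.copy()
    degenerate = []
    for var in variables:
        demeaned = df.groupby(COUNTRY)[var].transform(lambda s: s - s.mean())
        if np.nanmax(np.abs(demeaned.to_numpy()), initial=0.0) < tol:
            degenerate.append(var)
        df[var] = demeaned
    return PanelDataset(df, dict(panel.metadata)), degenerate


# ---------------------------------------------------------------------------
# estimators


def two_sls(
    eq: EquationSpec, instruments: tuple[str, ...], df: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-equation 2SLS.

    Returns (beta, residuals, XtPzX_inv).  Residuals use the ORIGINAL
    regressors.  With no endogenous RHS this reduces exactly to OLS.
    """
    names = list(eq.regressors)
    X = _matrix(df, eq.regressors)
    y = df[eq.dependent].to_numpy(dtype=float)
    Z = _matrix(df, instruments)
    if Z.shape[1] < X.shape[1]:
        raise EstimationError(
            f"{eq.name}: under-identified ({Z.shape[1]} instruments < "
            f"{X.shape[1]} regressors)"
        )
    _check_rank(X, names, f"equation {eq.name}")
    _check_rank(Z, list(instruments), f"equation {eq.name} instruments")
    Q, _ = np.linalg.qr(Z)
    Xhat = Q @ (Q.T @ X)  # projection of X on the instrument space
    XtPzX = Xhat.T @ X    # = X' Pz X since Pz idempotent
    beta = np.linalg.solve(XtPzX, Xhat.T @ y)
    resid = y - X @ beta
    return beta, resid, np.linalg.inv(XtPzX)


def residual_covariance(residuals: list[np.ndarray]) -> np.ndarray:
    """Cross-equation residual covariance, sigma_ij = e_i'e_j / n (no df correction)."""
    n = len(residuals[0])
    for e in residuals:
        if len(e) != n:
            raise ValueError("residual vectors must have equal length")
    E = np.column_stack(residuals)
    return E.T @ E / n


def _apply_fe(panel: PanelDataset, spec: SystemSpec) -> tuple[PanelDataset, SystemSpec]:
    used = sorted(
        ({v for eq in spec.equations
          for v in (eq.dependent, *eq.endogenous_rhs, *eq.exogenous_rhs)}
         | set(spec.instruments)) - {CONST}
    )
    panel, degenerate = within_transform(panel, used)
    if degenerate:
        warnings.warn(
            "within transformation annihilates time-invariant regressors, "
            f"dropped: {degenerate}", UserWarning,
        )
    drop = set(degenerate) | {CONST}
    eqs = tuple(
        replace(
            eq,
            endogenous_rhs=tuple(v for v in eq.endogenous_rhs if v not in drop),
            exogenous_rhs=tuple(v for v in eq.exogenous_rhs if v not in drop),
        )
        for eq in spec.equations
    )
    instruments = tuple(v for v in spec.instruments if v not in drop)
    return panel, SystemSpec(eqs, instruments, fe_mode="within")


def three_sls(
    spec: SystemSpec,
    panel: PanelDataset,
    method: str = "3sls",
) -> EstimationResult:
    """Estimate the system by 3SLS (or plain per-equation 2SLS).

    Stages: (1) project endogenous regressors on the instruments, (2) 2SLS
    per equation, (3) residual covariance from the 2SLS residuals, (4) one
    feasible-GLS step on the stacked system weighted by sigma^-1.  Standard
    errors come from the inverse weighted cross-product matrix.
    """
    if spec.fe_mode == "within":
        panel, spec = _apply_fe(panel, spec)
    df = estimation_frame(panel, spec)
    n = len(df)
    eqs = spec.equations
    Xs = [_matrix(df, eq.regressors) for eq in eqs]
    ys = [df[eq.dependent].to_numpy(dtype=float) for eq in eqs]
    first = [two_sls(eq, spec.instruments, df) for eq in eqs]
    sigma = residual_covariance([r for _, r, _ in first])
    dropped_to_2sls = False
    if method == "3sls":
        try:
            sigma_inv = np.linalg.inv(sigma)
        except np.linalg.LinAlgError:
            warnings.warn(
                "residual covariance is singular; falling back to 2SLS",
                UserWarning,
            )
            dropped_to_2sls = True
    if method == "3sls" and not dropped_to_2sls:
        Z = _matrix(df, spec.instruments)
        Q, _ = np.linalg.qr(Z)
        Xhats = [Q @ (Q.T @ X) for X in Xs]
        G = len(eqs)
        sizes = [X.shape[1] for X in Xs]
        offs = np.concatenate([[0], np.cumsum(sizes)])
        A = np.zeros((offs[-1], offs[-1]))
        c = np.zeros(offs[-1])
        for i in range(G):
            for j in range(G):
                block = sigma_inv[i, j] * (Xhats[i].T @ Xhats[j])
                A[offs[i]:offs[i + 1], offs[j]:offs[j + 1]] = block
                c[offs[i]:offs[i + 1]] += sigma_inv[i, j] * (Xhats[i].T @ ys[j])
        beta_stack = np.linalg.solve(A, c)
        cov_stack = np.linalg.inv(A)
        betas = [beta_stack[offs[i]:offs[i + 1]] for i in range(G)]
        covs = [cov_stack[offs[i]:offs[i + 1], offs[i]:offs[i + 1]] for i in range(G)]
        used_method = "3sls"
    else:
        # 2SLS: classical per-equation covariance sigma_ii * (X'PzX)^-1
        betas = [b for b, _, _ in first]
        covs = [sigma[i, i] * inv for i, (_, _, inv) in enumerate(first)]
        used_method = "2sls"

    coefficients: dict[str, list[CoefficientEstimate]] = {}
    r2: dict[str, float] = {}
    residuals = []
    for i, eq in enumerate(eqs):
        se = np.sqrt(np.diag(covs[i]))
        coefficients[eq.name] = [
            CoefficientEstimate(v, float(b), float(s))
            for v, b, s in zip(eq.regressors, betas[i], se)
        ]
        e = ys[i] - Xs[i] @ betas[i]
        residuals.append(e)
        sst = np.sum((ys[i] - ys[i].mean()) ** 2)
        r2[eq.name] = float(1 - np.sum(e**2) / sst) if sst > 0 else np.nan
    return EstimationResult(
        coefficients=coefficients,
        sigma=residual_covariance(residuals),
        r2=r2,
        n_obs=n,
        spec=spec,
        method=used_method,
        metadata={"first_stage_sigma": sigma, "fell_back_to_2sls": dropped_to_2sls},
    )


# ---------------------------------------------------------------------------
# system specification for the happiness-health model, and lag selection


def default_system_spec(
    k: int = 4,
    religion: str = "majority",
    education: str = "enrolment",
    health_var: str = "HLEB",
    fe_mode: str = "pooled",
    lsk_endogenous: bool = False,
) -> SystemSpec:
    """The two-equation specification in any of the four printed contexts.

    ``religion`` selects majority dummies or population shares; ``education``
    selects gross enrolments or per-student expenditures.  ``LSk`` (trailing
    k-year mean of LS) is predetermined by construction and included in the
    instrument set unless ``lsk_endogenous``.
    """
    rel = {
        "majority": ("BUDM", "CHRM", "HINM", "ISLM", "JUDM"),
        "percentage": ("BUDP", "CHRP", "HINP", "ISLP", "JUDP"),
    }[religion]
    edu = {
        "enrolment": ("GEP", "GES", "GET"),
        "expenditure": ("EEP", "EES", "EET"),
    }[education]
    lsk = f"LSk{k}"
    common = ("LNGDP", "GINI") + rel + edu
    ls_eq = EquationSpec(
        name="LS",
        dependent="LS",
        endogenous_rhs=(health_var,),
        exogenous_rhs=common + (CONST,),
    )
    hleb_eq = EquationSpec(
        name=health_var,
        dependent=health_var,
        endogenous_rhs=(lsk,) if lsk_endogenous else (),
        exogenous_rhs=common + (() if lsk_endogenous else (lsk,)) + (CONST,),
    )
    instruments = common + (CONST,) + (() if lsk_endogenous else (lsk,))
    return SystemSpec((ls_eq, hleb_eq), instruments, fe_mode=fe_mode)


def prune_degenerate_regressors(
    spec: SystemSpec, panel: PanelDataset, tol: float = 1e-12
) -> SystemSpec:
    """Drop regressors/instruments with (near-)zero variance in the sample.

    A dummy that never switches on (e.g. no majority country for a faith in
    a given draw) carries no information and would make the design matrix
    rank deficient; dropping it is the standard remedy and is logged.
    """
    df = estimation_frame(panel, spec)
    degenerate = {
        v
        for eq in spec.equations
        for v in eq.regressors
        if v != CONST and float(np.nanstd(df[v].to_numpy(dtype=float))) < tol
    }
    if not degenerate:
        return spec
    warnings.warn(f"dropping zero-variance regressors: {sorted(degenerate)}",
                  UserWarning)
    eqs = tuple(
        replace(
            eq,
            endogenous_rhs=tuple(v for v in eq.endogenous_rhs if v not in degenerate),
            exogenous_rhs=tuple(v for v in eq.exogenous_rhs if v not in degenerate),
        )
        for eq in spec.equations
    )
    instruments = tuple(v for v in spec.instruments if v not in degenerate)
    return SystemSpec(eqs, instruments, fe_mode=spec.fe_mode)


def select_lag(
    panel: PanelDataset,
    candidate_ks: list[int],
    spec_builder=default_system_spec,
    ls_variable: str = "LS",
    prune: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Refit the system for each k; return the R-squared table and the best k.

    All candidates are estimated on the SAME rows -- those where the deepest
    lag is defined -- so their fits are comparable.  The winner maximises the
    health-equation R-squared, ties broken toward smaller k.
    """
    from .prep import compute_lagged_mean

    ks = sorted(candidate_ks)
    work = panel
    for k in ks:
        work = compute_lagged_mean(work, ls_variable, k)
    deepest = f"{ls_variable}k{max(ks)}"
    work = PanelDataset(work.df.dropna(subset=[deepest]).reset_index(drop=True),
                        dict(work.metadata))
    rows = []
    for k in ks:
        spec = spec_builder(k=k)
        if prune:
            spec = prune_degenerate_regressors(spec, work)
        res = three_sls(spec, work)
        eq_names = [eq.name for eq in spec.equations]
        rows.append({"k": k, **{f"r2_{n}": res.r2[n] for n in eq_names}})
    table = pd.DataFrame(rows)
    health_col = [c for c in table.columns if c.startswith("r2_") and c != "r2_LS"][0]
    best_idx = table[health_col].round(12).idxmax()  # idxmax takes first (smallest k) tie
    return table, int(table.loc[best_idx, "k"])
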