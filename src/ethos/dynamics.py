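"""Coupled happiness-health linear dynamics: stability, shocks, convergence.

The estimated couplings -- eta3 (ladder points of life satisfaction per
year of healthy life expectancy) and theta3 (years of healthy life
expectancy per ladder point of the trailing k-year happiness mean) -- are
embedded in the deviation-from-equilibrium recursion

    hap[t] = eta3 * hea[t-1]
    hea[t] = (theta3 / k) * sum_{i=1..k} hap[t-i]

whose companion matrix governs stability: spectral radius < 1 means damped
(oscillating, since the couplings act with a delay) convergence to the
long-run equilibrium.  For k = 1 the matrix is [[0, eta3], [theta3, 0]]
with eigenvalues +/- sqrt(eta3 * theta3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class CouplingParams:
    eta3: float   # effect of health on happiness
    theta3: float  # effect of the lagged happiness mean on health
    k: int = 1     # lag depth of the happiness mean

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")


@dataclass
class DynamicalSystem:
    """Companion-matrix form of the lagged happiness-health recursion.

    State vector: (hap[t-1], ..., hap[t-k], hea[t-1]), dimension k+1.
    """

    params: CouplingParams
    matrix: np.ndarray
    state_labels: list[str]


@dataclass
class TrajectoryResult:
    hap: np.ndarray     # deviations of happiness from equilibrium, step 0 = shock
    hea: np.ndarray     # deviations of health
    shock_on: str
    magnitude: float
    oscillating: bool = field(init=False)

    def __post_init__(self) -> None:
        # A series oscillates if it crosses equilibrium repeatedly or, when the
        # couplings are positive (nonnegative transition matrix, deviations
        # one-signed), if it repeatedly rises and falls -- the damped ringing
        # seen after a happiness shock.
        self.oscillating = any(
            _sign_changes(s) >= 2 or _sign_changes(np.diff(s)) >= 2
            for s in (self.hap, self.hea)
        )


def _sign_changes(series: np.ndarray, tol: float = 1e-12) -> int:
    signs = np.sign(series[np.abs(series) > tol])
    return int(np.sum(signs[1:] != signs[:-1]))


def build_system(params: CouplingParams) -> DynamicalSystem:
    """Assemble the (k+1)x(k+1) transition matrix."""
    k = params.k
    A = np.zeros((k + 1, k + 1))
    A[0, k] = params.eta3                 # hap[t] = eta3 * hea[t-1]
    A[k, :k] = params.theta3 / k          # hea[t] = (theta3/k) * sum hap lags
    for i in range(1, k):                 # shift the hap lag window
        A[i, i - 1] = 1.0
    labels = [f"hap[t-{i}]" for i in range(1, k + 1)] + ["hea[t-1]"]
    return DynamicalSystem(params=params, matrix=A, state_labels=labels)


def eigen_analysis(
    system: DynamicalSystem,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Eigenvalues, unit eigenvectors (columns) and a stability flag.

    Eigenvectors are normalised to unit Euclidean length with the sign
    convention that the largest-magnitude component is positive.  The system
    is stable iff the spectral radius is below 1.
    """
    values, vectors = np.linalg.eig(system.matrix)
    order = np.argsort(values.real)
    values, vectors = values[order], vectors[:, order]
    vectors = vectors / np.linalg.norm(vectors, axis=0, keepdims=True)
    for j in range(vectors.shape[1]):
        lead = np.argmax(np.abs(vectors[:, j]))
        if vectors[lead, j].real < 0:
            vectors[:, j] = -vectors[:, j]
    if np.allclose(values.imag, 0):
        values = values.real
        vectors = vectors.real
    stable = bool(np.max(np.abs(values)) < 1)
    return values, vectors, stable


def simulate_shock(
    system: DynamicalSystem,
    shock_on: str = "hap",
    magnitude: float = 1.0,
    horizon: int = 40,
) -> TrajectoryResult:
    """Iterate x[t] = A x[t-1] from a one-coordinate shock.

    ``shock_on`` is ``'hap'`` (shock the most recent happiness lag) or
    ``'hea'``.  Step 0 of the returned series is the shock itself.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    if shock_on not in ("hap", "hea"):
        raise ValueError(f"shock_on must be 'hap' or 'hea', got {shock_on!r}")
    dim = system.matrix.shape[0]
    x = np.zeros(dim)
    x[0 if shock_on == "hap" else dim - 1] = magnitude
    hap = np.empty(horizon + 1)
    hea = np.empty(horizon + 1)
    hap[0], hea[0] = x[0], x[-1]
    for t in range(1, horizon + 1):
        x = system.matrix @ x
        hap[t], hea[t] = x[0], x[-1]
    return TrajectoryResult(hap=hap, hea=hea, shock_on=shock_on, magnitude=magnitude)


def convergence_time(
    trajectory: TrajectoryResult,
    rel_tol: float = 0.01,
    normalize: str = "series_amplitude",
) -> int | None:
    """First step from which both series stay within rel_tol of equilibrium.

    With ``normalize='series_amplitude'`` (default) each series' deviations
    are measured relative to that series' own peak amplitude, so the answer
    reflects the damping of the oscillation envelope regardless of the units
    of the two series; ``normalize='shock'`` measures both against the
    injected shock magnitude.  Returns None if the trajectory never settles
    within the simulated horizon.
    """
    if not (0 < rel_tol < 1) and rel_tol != 1:
        raise ValueError(f"rel_tol must be in (0, 1], got {rel_tol}")
    if trajectory.magnitude == 0:
        raise ValueError("convergence time is undefined for a zero shock")
    series = np.vstack([np.abs(trajectory.hap), np.abs(trajectory.hea)])
    if normalize == "series_amplitude":
        amp = series.max(axis=1, keepdims=True)
        amp[amp == 0] = 1.0
        scaled = series / amp
    elif normalize == "shock":
        scaled = series / abs(trajectory.magnitude)
    else:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    worst = scaled.max(axis=0)
    # smallest t such that every deviation from t onward is within tolerance
    tail_max = np.maximum.accumulate(worst[::-1])[::-1]
    within = tail_max <= rel_tol
    if not within.any():
        return None
    return int(np.argmax(within))


def standardized_cross_effect(
    theta3: float, mean_ls: float, mean_hleb: float
) -> tuple[float, float]:
    """Lagged-happiness effect on health rescaled by the sample means.

    Returns (full precision, truncated toward zero at two decimals); e.g.
    3.161 * 5.41 / 62 = 0.2758 -> 0.27.
    """
    if mean_hleb <= 0:
        raise ValueError("mean healthy life expectancy must be positive")
    value = theta3 * mean_ls / mean_hleb
    return value, math.trunc(value * 100) / 100


def long_run_equilibrium(
    eta3: float, theta3: float, a: float, b: float
) -> tuple[float, float]:
    """Fixed point of the structural system with LSk pinned at LS.

    Solves LS = a + eta3*HLEB, HLEB = b + theta3*LS where a and b collect
    the intercepts and exogenous terms of the two equations.
    """
    denom = 1.0 - eta3 * theta3
    if abs(denom) < 1e-12:
        raise ValueError("singular system: eta3 * theta3 = 1")
    ls = (a + eta3 * b) / denom
    hleb = b + theta3 * ls
    return ls, hleb
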