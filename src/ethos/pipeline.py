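"""End-to-end pipeline: simulate/load -> prepare -> estimate -> aggregate -> dynamics.

``run_pipeline`` sequences the stages with stage-boundary logging (record
counts, dropped countries) and writes a report bundle: coefficient CSVs,
the aggregation report, the dynamics JSON and a run manifest.  "Paper mode"
skips simulation/estimation and runs aggregation + dynamics directly off
the shipped printed tables, which takes well under a minute and needs no
external data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregation import (
    coupling_averages,
    cross_table_differences,
    education_level_sums,
    link_sign_matrix,
    load_all_tables,
    load_summary_stats,
    mean_significant_links,
    validate_coefficient_table,
)
from .dynamics import (
    CouplingParams,
    build_system,
    convergence_time,
    eigen_analysis,
    simulate_shock,
    standardized_cross_effect,
)
from .estimator import (
    default_system_spec,
    prune_degenerate_regressors,
    three_sls,
)
from .panel import PanelDataset, RELIGION_SHARES, read_panel, write_panel
from .prep import (
    compute_lagged_mean,
    derive_majority_dummies,
    enforce_balance,
    interpolate_missing,
)
from .synthetic import SyntheticConfig, generate_panel

log = logging.getLogger("ethos")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    ``input_panel`` is a CSV path or the literal string ``"synthetic"``;
    ``mode`` is ``"full"`` (simulate/prepare/estimate then aggregate the
    estimated tables) or ``"paper"`` (aggregate + dynamics from the shipped
    printed tables only).
    """

    mode: str = "paper"
    input_panel: str = "synthetic"
    k: int = 4
    alpha: float = 0.10
    fe_mode: str = "pooled"
    difference_policy: str = "raw"
    health_var: str = "HLEB"
    seed: int = 0
    out_dir: str = "results/run"
    horizon: int = 40
    rel_tol: float = 0.01

    def __post_init__(self) -> None:
        if self.mode not in ("paper", "full"):
            raise ValueError(f"mode must be 'paper' or 'full', got {self.mode!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.health_var not in ("HLEB", "LEB"):
            raise ValueError("health_var must be 'HLEB' or 'LEB'")
        if self.mode == "full" and self.input_panel != "synthetic":
            if not Path(self.input_panel).exists():
                raise ValueError(f"input panel not found: {self.input_panel}")


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def prepare_panel(
    panel: PanelDataset, k: int, health_var: str = "HLEB"
) -> PanelDataset:
    """The standard preprocessing chain on a raw panel.

    Interpolates interior gaps, adds majority dummies and the trailing
    k-year happiness mean, and balances on the variables the estimator
    needs.  ``LNGDP`` is derived from ``GDP`` if absent.
    """
    panel = interpolate_missing(panel)
    if "LNGDP" not in panel.df.columns and "GDP" in panel.df.columns:
        from .prep import log_transform

        panel = log_transform(panel, "GDP")
    share_vars = [v for v in RELIGION_SHARES if v in panel.df.columns]
    if share_vars and not all(v[:-1] + "M" in panel.df.columns for v in share_vars):
        panel = derive_majority_dummies(panel, share_vars)
    panel = compute_lagged_mean(panel, "LS", k)
    return panel


def run_estimation(
    panel: PanelDataset, config: PipelineConfig
) -> dict[tuple[str, str], "pd.DataFrame"]:
    """Fit the four context specifications; returns coefficient frames."""
    out = {}
    contexts = {
        "T3": ("majority", "enrolment"),
        "T4": ("percentage", "expenditure"),
        "T5": ("percentage", "enrolment"),
        "T6": ("majority", "expenditure"),
    }
    for tid, (religion, education) in contexts.items():
        spec = default_system_spec(
            k=config.k, religion=religion, education=education,
            health_var=config.health_var, fe_mode=config.fe_mode,
        )
        spec = prune_degenerate_regressors(spec, panel)
        result = three_sls(spec, panel)
        log.info("estimated %s (%s/%s): n=%d, R2=%s",
                 tid, religion, education, result.n_obs,
                 {k: round(v, 3) for k, v in result.r2.items()})
        for eq in result.coefficients:
            out[(tid, "LS" if eq == "LS" else "HLEB")] = result.table(eq)
    return out


def run_dynamics_stage(
    eta3: float, theta3: float, k: int, horizon: int, rel_tol: float,
    mean_ls: float, mean_hleb: float,
) -> dict:
    system = build_system(CouplingParams(eta3=eta3, theta3=theta3, k=k))
    values, vectors, stable = eigen_analysis(system)
    traj = simulate_shock(system, shock_on="hap", magnitude=1.0, horizon=horizon)
    steps = convergence_time(traj, rel_tol=rel_tol)
    full, truncated = standardized_cross_effect(theta3, mean_ls, mean_hleb)
    return {
        "couplings": {"eta3": eta3, "theta3": theta3, "k": k},
        "eigenvalues": np.asarray(values).real.tolist(),
        "eigenvectors": np.asarray(vectors).real.T.tolist(),
        "spectral_radius": float(np.max(np.abs(values))),
        "globally_stable": stable,
        "oscillating": traj.oscillating,
        "convergence_steps": steps,
        "rel_tol": rel_tol,
        "standardized_cross_effect": {"full": full, "truncated_2dp": truncated},
        "trajectory": {
            "hap": traj.hap.tolist(),
            "hea": traj.hea.tolist(),
        },
    }


def validate_fixtures(directory: str | Path | None = None) -> dict:
    """Consistency report for the shipped printed tables.

    Checks z = coef/SE and the 95% CI bounds cell by cell, and the printed
    summary-statistic orderings.  Report-only: inconsistent cells are
    listed, not raised.
    """
    tables = load_all_tables(directory)
    stats = load_summary_stats(
        Path(directory) / "table2_stats.csv" if directory else None
    )
    failures = []
    for table in tables.values():
        failures.extend(validate_coefficient_table(table))
    return {
        "n_tables": len(tables),
        "coefficient_cell_failures": failures,
        "summary_ordering_anomalies": stats.check_ordering(),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured pipeline and write the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
    }
    stats = load_summary_stats()

    try:
        if config.mode == "paper":
            tables = load_all_tables()
        else:
            if config.input_panel == "synthetic":
                panel, params = generate_panel(SyntheticConfig(seed=config.seed,
                                                               k=config.k))
                (out_dir / "true_params.json").write_text(
                    json.dumps(params.to_dict(), indent=2)
                )
            else:
                panel = read_panel(config.input_panel)
            log.info("input panel: %d records, %d countries",
                     panel.n_obs, len(panel.countries))
            panel = prepare_panel(panel, config.k, config.health_var)
            years = panel.years
            panel_b = enforce_balance(
                panel, (years[0] + config.k, years[-1]),
                variables=None,
            )
            log.info("balanced sample: %d records (%s dropped)",
                     panel_b.n_obs,
                     len(panel_b.metadata["balance_report"]["dropped_countries"]))
            write_panel(panel_b, out_dir / "prepared.csv")
            frames = run_estimation(panel_b, config)
            from .aggregation import CoefficientTable, TABLE_CONTEXTS

            tables = {
                key: CoefficientTable(key[0], key[1], frame,
                                      dict(TABLE_CONTEXTS[key[0]]))
                for key, frame in frames.items()
            }
    except Exception as exc:  # noqa: BLE001 - annotate with stage context
        raise PipelineError(f"estimation stage failed: {exc}") from exc

    try:
        for (tid, eq), table in tables.items():
            table.entries.to_csv(out_dir / f"coef_{tid}_{eq}.csv", index=False)
        link_sign_matrix(tables, config.alpha).to_csv(out_dir / "sign_matrix.csv")
        aggregation = {
            "alpha": config.alpha,
            "mean_significant_links": {
                f"{tid}/{eq}/{group}": mean_significant_links(
                    tables[(tid, eq)], group, config.alpha
                )
                for tid in ("T3", "T4", "T5", "T6")
                for eq in ("LS", "HLEB")
                for group in ("REL", "EDU")
            },
            "education_level_sums": {
                "majority": {
                    eq: education_level_sums(
                        tables[("T3", eq)], tables[("T6", eq)], stats
                    ).to_dict("records")
                    for eq in ("LS", "HLEB")
                },
                "minority": {
                    eq: education_level_sums(
                        tables[("T5", eq)], tables[("T4", eq)], stats
                    ).to_dict("records")
                    for eq in ("LS", "HLEB")
                },
            },
            "religion_context_differences": {
                eq: cross_table_differences(
                    tables[("T3", eq)], tables[("T5", eq)],
                    policy=config.difference_policy, alpha=config.alpha,
                    align="intersection",
                ).to_dict("records")
                for eq in ("LS", "HLEB")
            },
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"aggregation stage failed: {exc}") from exc

    try:
        couplings = coupling_averages(tables)
        dyn = run_dynamics_stage(
            round(couplings["eta3"], 3), round(couplings["theta3"], 3),
            k=1, horizon=config.horizon, rel_tol=config.rel_tol,
            mean_ls=stats.mean("LS"), mean_hleb=stats.mean("HLEB"),
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"dynamics stage failed: {exc}") from exc

    report = {"manifest": manifest, "aggregation": aggregation, "dynamics": dyn}
    (out_dir / "aggregation.json").write_text(_dumps(aggregation))
    (out_dir / "dynamics.json").write_text(_dumps(dyn))
    (out_dir / "manifest.json").write_text(_dumps(manifest))
    pd.DataFrame(
        {"step": range(len(dyn["trajectory"]["hap"])),
         "hap_dev": dyn["trajectory"]["hap"],
         "hea_dev": dyn["trajectory"]["hea"]}
    ).to_csv(out_dir / "trajectory.csv", index=False)
    return report


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _dumps(obj) -> str:
    return json.dumps(_sanitize(obj), indent=2)
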