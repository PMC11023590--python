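import numpy as np
import pandas as pd
import pytest

from ethos.panel import PanelDataset
from ethos.estimator import (
    CONST,
    EquationSpec,
    EstimationError,
    SystemSpec,
    default_system_spec,
    estimation_frame,
    prune_degenerate_regressors,
    residual_covariance,
    select_lag,
    three_sls,
    two_sls,
    within_transform,
)
from ethos.synthetic import SyntheticConfig, generate_panel

from conftest import make_panel


def brute_force_3sls(eqs, instruments, df):
    """Literal stacked weighted normal equations, as an independent oracle.

    beta = [X'(S^-1 (x) Pz)X]^-1 X'(S^-1 (x) Pz)y with X block-diagonal,
    built explicitly with numpy.kron -- no shortcuts shared with the
    implementation under test.
    """

    def mat(names):
        return np.column_stack(
            [np.ones(len(df)) if n == CONST else df[n].to_numpy() for n in names]
        )

    Z = mat(instruments)
    Pz = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
    Xs = [mat(eq.regressors) for eq in eqs]
    ys = [df[eq.dependent].to_numpy() for eq in eqs]
    # first-round 2SLS residuals for sigma
    resids = []
    for X, y in zip(Xs, ys):
        b = np.linalg.solve(X.T @ Pz @ X, X.T @ Pz @ y)
        resids.append(y - X @ b)
    n = len(df)
    S = np.array([[ri @ rj / n for rj in resids] for ri in resids])
    X_block = np.zeros((2 * n, sum(X.shape[1] for X in Xs)))
    X_block[:n, : Xs[0].shape[1]] = Xs[0]
    X_block[n:, Xs[0].shape[1]:] = Xs[1]
    y_stack = np.concatenate(ys)
    W = np.kron(np.linalg.inv(S), Pz)
    A = X_block.T @ W @ X_block
    beta = np.linalg.solve(A, X_block.T @ W @ y_stack)
    return beta, np.linalg.inv(A)


def tiny_system_panel(seed=0, n=24):
    """A little two-equation dataset with an endogenous regressor."""
    rng = np.random.default_rng(seed)
    x1, x2, z = rng.normal(size=(3, n))
    e = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=n)
    y2 = 0.5 + 1.2 * x1 - 0.7 * x2 + 2.0 * z + e[:, 1]
    y1 = -1.0 + 0.8 * y2 + 0.5 * x1 + e[:, 0]
    df = pd.DataFrame({"country": [f"C{i}" for i in range(n)], "year": 2000,
                       "y1": y1, "y2": y2, "x1": x1, "x2": x2, "z": z})
    eq1 = EquationSpec("first", "y1", ("y2",), ("x1", CONST))
    eq2 = EquationSpec("second", "y2", (), ("x1", "x2", "z", CONST))
    instruments = ("x1", "x2", "z", CONST)
    return df, (eq1, eq2), instruments


class TestWithinTransform:
    def test_demeans_by_country(self):
        panel = make_panel({"A": {2000 + i: {"X": v} for i, v in enumerate([1, 2, 3])},
                            "B": {2000 + i: {"X": v} for i, v in enumerate([10, 20, 30])}})
        out, degenerate = within_transform(panel, ["X"])
        np.testing.assert_allclose(
            out.df.sort_values(["country", "year"])["X"],
            [-1, 0, 1, -10, 0, 10],
        )
        assert degenerate == []

    def test_time_invariant_dummy_annihilated_and_flagged(self):
        panel = make_panel({"A": {y: {"D": 1.0, "X": float(y)} for y in range(2000, 2004)},
                            "B": {y: {"D": 0.0, "X": 2.0 * y} for y in range(2000, 2004)}})
        out, degenerate = within_transform(panel, ["D", "X"])
        assert degenerate == ["D"]
        np.testing.assert_allclose(out.df["D"], 0.0)


class TestTwoSLS:
    def test_exact_line_recovered_without_endogeneity(self):
        df = pd.DataFrame({"y": [2.0, 4.0, 6.0], "x": [1.0, 2.0, 3.0]})
        eq = EquationSpec("e", "y", (), ("x",))
        beta, resid, _ = two_sls(eq, ("x",), df)
        assert beta[0] == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_closed_form_just_identified_ratio(self):
        # single regressor, single instrument, no intercept: beta = Szy/Szx
        df = pd.DataFrame({"z": [1.0, 2.0, 3.0], "x": [1.0, 2.0, 4.0],
                           "y": [2.0, 4.0, 7.0]})
        eq = EquationSpec("e", "y", ("x",), ())
        beta, _, _ = two_sls(eq, ("z",), df)
        assert beta[0] == pytest.approx(31 / 17, abs=1e-12)

    def test_all_exogenous_instruments_equal_ols(self):
        df, (eq1, eq2), instruments = tiny_system_panel()
        beta_iv, _, _ = two_sls(eq2, instruments, df)
        X = np.column_stack([df["x1"], df["x2"], df["z"], np.ones(len(df))])
        beta_ols = np.linalg.lstsq(X, df["y2"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(beta_iv, beta_ols, atol=1e-10)

    def test_under_identification_rejected(self):
        df, (eq1, _), _ = tiny_system_panel()
        with pytest.raises(EstimationError, match="under-identified"):
            two_sls(eq1, ("x1",), df)

    def test_rank_deficiency_names_collinear_column(self):
        df, (eq1, eq2), instruments = tiny_system_panel()
        df["x1_copy"] = df["x1"]
        eq = EquationSpec("second", "y2", (), ("x1", "x1_copy", CONST))
        with pytest.raises(EstimationError, match="x1"):
            two_sls(eq, instruments + ("x1_copy",), df)


class TestResidualCovariance:
    def test_hand_examples(self):
        e1 = np.array([1.0, -1.0])
        e2 = np.array([1.0, 1.0])
        np.testing.assert_allclose(residual_covariance([e1, e2]),
                                   [[1.0, 0.0], [0.0, 1.0]])
        same = residual_covariance([e1, e1])
        assert same[0, 0] == same[0, 1] == same[1, 1]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            residual_covariance([np.ones(3), np.ones(4)])


class TestThreeSLS:
    def test_matches_brute_force_oracle(self):
        for seed in range(4):
            df, eqs, instruments = tiny_system_panel(seed=seed, n=28)
            panel = PanelDataset(df.assign(year=range(2000, 2000 + len(df))))
            spec = SystemSpec(eqs, instruments)
            res = three_sls(spec, panel)
            beta_oracle, cov_oracle = brute_force_3sls(eqs, instruments, df)
            mine = np.concatenate(
                [[c.estimate for c in res.coefficients[eq.name]] for eq in eqs]
            )
            np.testing.assert_allclose(mine, beta_oracle, atol=1e-8)
            se_oracle = np.sqrt(np.diag(cov_oracle))
            se_mine = np.concatenate(
                [[c.std_err for c in res.coefficients[eq.name]] for eq in eqs]
            )
            np.testing.assert_allclose(se_mine, se_oracle, atol=1e-8)

    def test_identical_exogenous_sets_degenerate_to_ols(self):
        # classical SUR result: same regressors in every equation => GLS = OLS
        rng = np.random.default_rng(5)
        n = 40
        x = rng.normal(size=n)
        y1 = 1 + 2 * x + rng.normal(size=n)
        y2 = -1 + 3 * x + rng.normal(size=n)
        df = pd.DataFrame({"country": "A", "year": range(n), "y1": y1, "y2": y2,
                           "x": x})
        eqs = (EquationSpec("a", "y1", (), ("x", CONST)),
               EquationSpec("b", "y2", (), ("x", CONST)))
        res = three_sls(SystemSpec(eqs, ("x", CONST)), PanelDataset(df))
        X = np.column_stack([x, np.ones(n)])
        for name, y in (("a", y1), ("b", y2)):
            ols = np.linalg.lstsq(X, y, rcond=None)[0]
            mine = [c.estimate for c in res.coefficients[name]]
            np.testing.assert_allclose(mine, ols, atol=1e-10)

    def test_z_p_ci_invariants(self, small_panel):
        panel, _ = small_panel
        from ethos.pipeline import prepare_panel

        prepared = prepare_panel(panel, 4)
        spec = prune_degenerate_regressors(default_system_spec(k=4), prepared)
        res = three_sls(spec, prepared)
        for eq_coefs in res.coefficients.values():
            for c in eq_coefs:
                assert c.z == pytest.approx(c.estimate / c.std_err)
                assert c.ci_low == pytest.approx(c.estimate - 1.959964 * c.std_err)
                assert 0 <= c.p_value <= 1
        assert np.allclose(res.sigma, res.sigma.T)
        assert np.all(np.linalg.eigvalsh(res.sigma) >= -1e-12)

    def test_scale_equivariance(self):
        df, eqs, instruments = tiny_system_panel(seed=2)
        panel = PanelDataset(df.assign(year=range(len(df))))
        spec = SystemSpec(eqs, instruments)
        base = three_sls(spec, panel)
        scaled_df = df.assign(x2=df["x2"] * 10.0)
        scaled = three_sls(spec, PanelDataset(scaled_df.assign(year=range(len(df)))))
        c0 = base.coefficient("second", "x2")
        c1 = scaled.coefficient("second", "x2")
        assert c1.estimate == pytest.approx(c0.estimate / 10.0)
        assert c1.std_err == pytest.approx(c0.std_err / 10.0)


class TestEndogeneityAndRecovery:
    def test_ols_biased_system_estimator_not(self):
        """With correlated errors, single-equation OLS overstates the
        health->happiness coupling; the system estimator does not."""
        from ethos.pipeline import prepare_panel
        from ethos.synthetic import error_cov_from_corr

        ols_err, sys_err = [], []
        cov = error_cov_from_corr(0.60, 2.50, 0.5)
        for seed in range(12):
            panel, params = generate_panel(
                SyntheticConfig(n_countries=100, n_years=21, seed=seed,
                                error_cov=cov)
            )
            prepared = prepare_panel(panel, 4)
            spec = prune_degenerate_regressors(default_system_spec(k=4), prepared)
            df = estimation_frame(prepared, spec)
            eq = spec.equations[0]
            ols_eq = EquationSpec("LS", "LS", (), eq.endogenous_rhs + eq.exogenous_rhs)
            b_ols, _, _ = two_sls(ols_eq, ols_eq.exogenous_rhs, df)
            res = three_sls(spec, prepared)
            truth = params.eta["HLEB"]
            ols_err.append(b_ols[0] - truth)
            sys_err.append(res.coefficient("LS", "HLEB").estimate - truth)
        assert abs(np.mean(ols_err)) > abs(np.mean(sys_err))
        assert abs(np.mean(ols_err)) > 0.02  # the bias is real, not noise


class TestLagSelection:
    def test_single_candidate_single_row(self, small_panel):
        panel, _ = small_panel
        table, best = select_lag(panel, [1])
        assert len(table) == 1 and best == 1

    def test_noise_free_panel_identifies_true_lag_exactly(self):
        cfg = SyntheticConfig(n_countries=12, n_years=14, seed=4, k=3,
                              error_cov=np.zeros((2, 2)))
        panel, _ = generate_panel(cfg)
        table, best = select_lag(panel, [2, 3, 4])
        assert best == 3
        r2 = table.set_index("k")["r2_HLEB"]
        assert r2.loc[3] == pytest.approx(1.0, abs=1e-9)
        assert (r2.drop(3) < 1.0 - 1e-9).all()
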