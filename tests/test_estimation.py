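"""Penalized nodewise regression: solver oracles, CV selection, network fit."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso

from clpnet.estimation import (
    CLPNetwork,
    FitConfig,
    ZeroVarianceError,
    fit_clpn,
    fit_clpn_arrays,
    fit_node,
    lambda_grid_max,
    lasso_path,
    standardize_panel,
)
from clpnet.items import node_ids
from clpnet.panel import ScoringStateError

from conftest import make_panel


def _pop_z(x):
    return (x - x.mean(axis=0)) / x.std(axis=0)


class TestStandardize:
    def test_symptoms_are_z_scored(self, analysis_panel):
        d = standardize_panel(analysis_panel)
        assert np.allclose(d.Y1.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(d.Y1.std(axis=0), 1, atol=1e-12)
        assert np.allclose(d.Y2.std(axis=0), 1, atol=1e-12)

    def test_categoricals_are_dummy_coded_against_first_level(self, analysis_panel):
        d = standardize_panel(analysis_panel)
        assert "ethnicity_2" in d.cov_labels  # Han (1) is the reference
        assert "ethnicity_1" not in d.cov_labels
        edu = [c for c in d.cov_labels if c.startswith("parent_education")]
        assert edu == ["parent_education_2", "parent_education_3",
                       "parent_education_4"]

    def test_scaling_round_trips(self, analysis_panel):
        d = standardize_panel(analysis_panel)
        raw = analysis_panel.symptom_values(wave="T1")
        back = d.scaling["T1"].inverse(d.Y1)
        assert np.allclose(back, raw, atol=1e-12)

    def test_zero_variance_column_is_named(self, analysis_panel):
        panel = analysis_panel.copy()
        panel.df["C_D5_T1"] = 2.0
        with pytest.raises(ZeroVarianceError, match="C_D5_T1"):
            standardize_panel(panel)


class TestLassoPath:
    def test_soft_threshold_on_single_predictor(self):
        # unit-variance predictor with exact sample correlation 0.5:
        # beta = S(0.5, 0.2) = 0.3
        n = 40
        rng = np.random.default_rng(0)
        x = _pop_z(rng.standard_normal((n, 1)))
        v = rng.standard_normal(n)
        v -= v.mean() + x[:, 0] * (x[:, 0] @ v) / n  # orthogonal to x
        y = 0.5 * x[:, 0] + v
        beta = lasso_path(y, x, lam=0.2)
        assert beta[0] == pytest.approx(0.3, abs=1e-9)

    def test_null_model_at_lambda_max(self):
        rng = np.random.default_rng(1)
        X = _pop_z(rng.standard_normal((100, 8)))
        y = rng.standard_normal(100)
        lmax = np.abs(X.T @ y).max() / 100
        assert np.all(lasso_path(y, X, lam=lmax) == 0.0)
        assert np.all(lasso_path(y, X, lam=2 * lmax) == 0.0)

    def test_matches_ols_at_zero_penalty(self):
        rng = np.random.default_rng(2)
        X = _pop_z(rng.standard_normal((200, 6)))
        y = rng.standard_normal(200)
        beta = lasso_path(y, X, lam=0.0)
        ols = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(beta, ols, atol=1e-6)

    def test_orthonormal_design_equals_soft_thresholded_ols(self):
        rng = np.random.default_rng(3)
        n, p = 50, 5
        Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
        X = Q * np.sqrt(n)  # X'X/n = I exactly
        y = rng.standard_normal(n)
        ols = X.T @ y / n
        for lam in (0.01, 0.05, 0.2):
            beta = lasso_path(y, X, lam=lam)
            oracle = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
            assert np.allclose(beta, oracle, atol=1e-8)

    @pytest.mark.parametrize("lam", [0.01, 0.1])
    def test_agrees_with_independent_solver(self, lam):
        rng = np.random.default_rng(4)
        X = _pop_z(rng.standard_normal((300, 10)) @ rng.standard_normal((10, 10)))
        y = rng.standard_normal(300)
        y -= y.mean()
        ours = lasso_path(y, X, lam=lam)
        ref = Lasso(alpha=lam, fit_intercept=False, tol=1e-12).fit(X, y).coef_
        assert np.allclose(ours, ref, atol=1e-6)

    def test_unpenalized_columns_follow_ols_within_active_model(self):
        rng = np.random.default_rng(5)
        X = _pop_z(rng.standard_normal((500, 4)))
        y = 0.5 * X[:, 3] + rng.standard_normal(500)
        y -= y.mean()
        pf = np.array([1.0, 1.0, 1.0, 0.0])
        beta = lasso_path(y, X, pf, lam=10.0)  # huge penalty kills cols 0-2
        assert np.all(beta[:3] == 0.0)
        ols3 = (X[:, 3] @ y) / (X[:, 3] @ X[:, 3])
        assert beta[3] == pytest.approx(ols3, abs=1e-7)

    def test_lambda_grid_max_respects_unpenalized_block(self):
        rng = np.random.default_rng(6)
        X = _pop_z(rng.standard_normal((400, 5)))
        y = X[:, 0] + rng.standard_normal(400)
        y -= y.mean()
        pf = np.array([0.0, 1.0, 1.0, 1.0, 1.0])
        G, c = X.T @ X / 400, X.T @ y / 400
        lmax = lambda_grid_max(G, c, pf)
        beta = lasso_path(y, X, pf, lam=lmax * (1 + 1e-9))
        assert np.all(beta[1:] == 0.0) and beta[0] != 0.0


class TestFitNode:
    def test_pure_noise_outcome_selects_nothing_under_1se(self, analysis_panel):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            Y1 = _pop_z(rng.standard_normal((2000, 16)))
            Y2 = _pop_z(rng.standard_normal((2000, 16)))
            cfg = FitConfig(fold_seed=seed, lambda_rule="1se")
            net = fit_clpn_arrays(Y1, Y2, None, cfg, node_ids("boy", "father"),
                                  outcomes=np.array([0]))
            hits += np.all(net.B_hat[:, 0] == 0.0)
        assert hits >= 9

    def test_pure_noise_under_min_rule_selects_little(self):
        spurious = []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            Y1 = _pop_z(rng.standard_normal((2000, 16)))
            Y2 = _pop_z(rng.standard_normal((2000, 16)))
            cfg = FitConfig(fold_seed=seed)
            net = fit_clpn_arrays(Y1, Y2, None, cfg, node_ids("boy", "father"),
                                  outcomes=np.array([0]))
            spurious.append((net.B_hat[:, 0] != 0).sum())
        assert np.mean(spurious) < 3  # CV-min retains a few tiny coefficients

    def test_single_signal_is_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            Y1 = _pop_z(rng.standard_normal((2000, 16)))
            noise = rng.standard_normal(2000) * np.sqrt(1 - 0.25)
            Y2 = np.tile(rng.standard_normal(2000), (16, 1)).T
            Y2[:, 5] = 0.5 * Y1[:, 2] + noise
            Y2 = _pop_z(Y2)
            cfg = FitConfig(fold_seed=seed)
            net = fit_clpn_arrays(Y1, Y2, None, cfg, node_ids("boy", "father"),
                                  outcomes=np.array([5]))
            col = net.B_hat[:, 5]
            others = np.delete(col, 2)
            if abs(col[2] - 0.5) < 0.1 and np.abs(others).max() < 0.08:
                hits += 1
        assert hits >= 9

    def test_cv_curve_is_finite_with_a_minimizer(self, analysis_panel):
        design = standardize_panel(analysis_panel, include_covariates=False)
        coef, lam, curve = fit_node(0, design, FitConfig(fold_seed=1))
        assert np.isfinite(curve["cv_mse"]).all()
        assert lam in curve["lambda"]
        assert lam == curve["lambda"][np.argmin(curve["cv_mse"])]

    def test_needs_more_rows_than_folds(self):
        panel = make_panel(8, seed=50)
        with pytest.raises(ValueError, match="n_folds"):
            fit_clpn(panel, FitConfig(n_folds=10), include_covariates=False)


class TestFitCLPN:
    def test_shape_and_communities(self, fitted_network):
        assert fitted_network.B_hat.shape == (16, 16)
        comm = list(fitted_network.community.values())
        assert comm.count("child") == 8 and comm.count("parent") == 8

    def test_deterministic_given_config(self, analysis_panel, fitted_network):
        again = fit_clpn(analysis_panel, FitConfig(fold_seed=7),
                         include_covariates=False)
        np.testing.assert_array_equal(again.B_hat, fitted_network.B_hat)
        np.testing.assert_array_equal(
            again.lambda_per_node, fitted_network.lambda_per_node
        )

    def test_fold_seed_changes_fit(self, analysis_panel, fitted_network):
        other = fit_clpn(analysis_panel, FitConfig(fold_seed=8),
                         include_covariates=False)
        assert not np.array_equal(other.B_hat, fitted_network.B_hat)

    def test_covariate_column_order_does_not_move_edges(self, analysis_panel):
        d = standardize_panel(analysis_panel)
        nodes = node_ids("boy", "father")
        cfg = FitConfig(fold_seed=3)
        a = fit_clpn_arrays(d.Y1, d.Y2, d.X_cov, cfg, nodes,
                            cov_names=d.cov_labels)
        perm = np.arange(d.X_cov.shape[1])[::-1]
        b = fit_clpn_arrays(d.Y1, d.Y2, d.X_cov[:, perm], cfg, nodes,
                            cov_names=[d.cov_labels[i] for i in perm])
        np.testing.assert_allclose(a.B_hat, b.B_hat, atol=1e-8)

    def test_refuses_unscored_panel(self, analysis_panel):
        raw = analysis_panel.copy()
        raw.metadata["scored"] = False
        with pytest.raises(ScoringStateError):
            fit_clpn(raw, FitConfig())

    def test_covariate_coefficients_kept_out_of_the_network(self, analysis_panel):
        net = fit_clpn(analysis_panel, FitConfig(fold_seed=2))
        assert net.B_hat.shape == (16, 16)
        assert set(net.covariate_coefs.index) >= {"child_age", "ethnicity_2"}
        assert net.covariate_coefs.shape[1] == 16

    def test_save_load_round_trip(self, fitted_network, tmp_path):
        fitted_network.save(tmp_path / "net")
        back = CLPNetwork.load(tmp_path / "net")
        np.testing.assert_allclose(back.B_hat, fitted_network.B_hat, atol=1e-9)
        assert back.node_names == fitted_network.node_names
        assert back.n_used == fitted_network.n_used
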