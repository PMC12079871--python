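"""Node-wise LASSO estimation, thresholding, and edge summaries.

The fixed-penalty solver is checked against an independent from-scratch
coordinate-descent oracle and against closed-form soft-thresholding on
orthonormal designs.
"""

import dataclasses

import numpy as np
import pytest

from clpnet.config import AnalysisConfig
from clpnet.estimation import (CLPNResult, estimate_clpn, fit_node_lasso,
                               summarize_edges, threshold_edges)
from clpnet.preprocess import transform_dataset
from clpnet.simulate import SyntheticSpec, generate_panel

from conftest import small_nodes, strong_spec


def cd_lasso_oracle(X, y, lam, n_iter=2000, tol=1e-12):
    """Cyclic coordinate descent for (1/2n)||y - Xb - b0||^2 + lam*||b||_1.

    Independent reference implementation: no path tricks, no library calls.
    Assumes X columns already standardized; fits the intercept as mean(y).
    """
    n, p = X.shape
    yc = y - y.mean()
    b = np.zeros(p)
    col_sq = (X ** 2).sum(axis=0) / n
    r = yc.copy()
    for _ in range(n_iter):
        b_old = b.copy()
        for j in range(p):
            r = r + X[:, j] * b[j]
            rho = X[:, j] @ r / n
            b[j] = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_sq[j]
            r = r - X[:, j] * b[j]
        if np.max(np.abs(b - b_old)) < tol:
            break
    return b


def standardize(X):
    return (X - X.mean(0)) / X.std(0)


class TestFitNodeLasso:
    def test_penalty_at_or_above_lambda_max_zeroes_everything(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 6))
        y = X @ np.array([0.5, -0.3, 0, 0, 0.2, 0]) + rng.normal(size=100)
        Xs = standardize(X)
        lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / 100
        fit = fit_node_lasso(y, X, folds=5, fixed_penalty=lam_max * 1.0001)
        assert all(v == 0.0 for v in fit.coefficients.values())

    def test_zero_penalty_recovers_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 4))
        y = X @ np.array([0.4, -0.2, 0.1, 0.0]) + rng.normal(size=120)
        fit = fit_node_lasso(y, X, folds=5, fixed_penalty=0.0)
        Xs = standardize(X)
        Z = np.column_stack([np.ones(120), Xs])
        ols = np.linalg.lstsq(Z, y, rcond=None)[0][1:]
        got = np.array(list(fit.coefficients.values()))
        np.testing.assert_allclose(got, ols, atol=1e-6)

    def test_orthonormal_design_soft_thresholds_ols(self):
        rng = np.random.default_rng(2)
        n, p = 200, 5
        A = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
        Q, _ = np.linalg.qr(A)
        X = Q[:, 1:] * np.sqrt(n)  # mean-zero, unit-variance, orthogonal
        beta = np.array([0.6, -0.4, 0.25, 0.0, 0.1])
        y = X @ beta + rng.normal(size=n)
        lam = 0.15
        fit = fit_node_lasso(y, X, folds=5, fixed_penalty=lam)
        ols = X.T @ (y - y.mean()) / n
        expected = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
        got = np.array(list(fit.coefficients.values()))
        np.testing.assert_allclose(got, expected, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_coordinate_descent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 200, 5
        X = rng.normal(size=(n, p)) @ (np.eye(p) + 0.3)
        y = X @ rng.normal(scale=0.3, size=p) + rng.normal(size=n)
        for lam in (0.02, 0.1):
            fit = fit_node_lasso(y, X, folds=5, fixed_penalty=lam)
            oracle = cd_lasso_oracle(standardize(X), y, lam)
            got = np.array(list(fit.coefficients.values()))
            np.testing.assert_allclose(got, oracle, atol=1e-6)

    def test_unpenalized_covariate_matches_masked_oracle(self):
        """Frisch-Waugh residualization equals joint masked coordinate descent."""
        rng = np.random.default_rng(11)
        n = 300
        X = rng.normal(size=(n, 4))
        y = X @ np.array([0.5, 0.0, -0.3, 0.4]) + rng.normal(size=n)
        lam = 0.08
        mask = np.array([True, True, True, False])
        fit = fit_node_lasso(y, X, folds=5, fixed_penalty=lam,
                             penalize_mask=mask, n_node_predictors=3)

        # oracle: cyclic CD where the unpenalized coordinate skips shrinkage
        Xs = standardize(X)
        yc = y - y.mean()
        b = np.zeros(4)
        col_sq = (Xs ** 2).sum(axis=0) / n
        r = yc.copy()
        for _ in range(5000):
            b_old = b.copy()
            for j in range(4):
                r = r + Xs[:, j] * b[j]
                rho = Xs[:, j] @ r / n
                thr = 0.0 if not mask[j] else lam
                b[j] = np.sign(rho) * max(abs(rho) - thr, 0.0) / col_sq[j]
                r = r - Xs[:, j] * b[j]
            if np.max(np.abs(b - b_old)) < 1e-13:
                break
        got = np.array(list(fit.coefficients.values()) +
                       list(fit.covariate_coefficients.values()))
        np.testing.assert_allclose(got, b, atol=1e-6)

    def test_support_monotone_in_penalty(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(150, 8))
        y = X @ rng.normal(scale=0.3, size=8) + rng.normal(size=150)
        small = fit_node_lasso(y, X, folds=5, fixed_penalty=1e-4)
        large = fit_node_lasso(y, X, folds=5, fixed_penalty=0.2)
        sup_small = {k for k, v in small.coefficients.items() if v != 0}
        sup_large = {k for k, v in large.coefficients.items() if v != 0}
        assert sup_large <= sup_small

    def test_folds_exceeding_n_rejected(self):
        X = np.random.default_rng(0).normal(size=(4, 2))
        with pytest.raises(ValueError, match="folds"):
            fit_node_lasso(X[:, 0], X, folds=10)

    def test_selected_penalty_on_grid_and_r2_bounded(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 5))
        y = X @ np.array([0.5, 0, 0, -0.4, 0]) + rng.normal(size=100)
        fit = fit_node_lasso(y, X, folds=5, grid_size=30, seed=1)
        assert fit.selected_penalty in fit.penalty_grid
        assert 0.0 <= fit.r_squared_full <= 1.0


class TestEstimateCLPN:
    def test_recovers_planted_strong_edges(self, fast_config):
        spec = strong_spec(2000, p_per_construct=2, weights=(0.5, 0.5),
                           seed=0)
        ds = generate_panel(spec, seed=10)
        res = estimate_clpn(transform_dataset(ds), fast_config)
        off = ~np.eye(4, dtype=bool)
        for i, j in zip(*np.nonzero((spec.true_b != 0) & off)):
            assert res.weights[i, j] > 0.1  # in support, sign-correct

    def test_null_generator_yields_sparse_thresholded_network(self,
                                                              fast_config):
        nodes = small_nodes(2, 2)
        spec = SyntheticSpec(n_subjects=1500, nodes=nodes,
                             true_b=np.eye(4) * 0.3, r_between=0.0)
        ds = generate_panel(spec, seed=5)
        res = estimate_clpn(transform_dataset(ds), fast_config)
        assert np.all(np.abs(res.crosslagged_weights()) < 0.1)
        edges = threshold_edges(res)
        assert len(edges) <= 6  # near-empty after thresholding

    def test_row_permutation_invariance(self, fast_config):
        spec = strong_spec(300, seed=2)
        ds = generate_panel(spec, seed=3)
        tds = transform_dataset(ds)
        res = estimate_clpn(tds, fast_config)
        rng = np.random.default_rng(9)
        perm = rng.permutation(ds.n_subjects)
        res_p = estimate_clpn(tds.subset(perm), fast_config)
        np.testing.assert_allclose(res.weights, res_p.weights, atol=1e-8)

    def test_reproducible_serialization(self, fast_config):
        spec = strong_spec(250, seed=4)
        ds = transform_dataset(generate_panel(spec, seed=6))
        a = estimate_clpn(ds, fast_config).to_json()
        b = estimate_clpn(ds, fast_config).to_json()
        assert a == b

    def test_means_recomputable_from_weights(self, fast_config):
        spec = strong_spec(300, seed=1)
        ds = transform_dataset(generate_panel(spec, seed=2))
        res = estimate_clpn(ds, fast_config)
        p = res.n_nodes
        assert res.autoregressive_mean == pytest.approx(
            np.diag(res.weights).mean())
        off = ~np.eye(p, dtype=bool)
        assert res.crosslagged_mean == pytest.approx(
            res.weights[off].mean())


def make_result(weights, constructs=None):
    p = len(weights)
    ids = [f"N{i}" for i in range(p)]
    return CLPNResult(weights=np.asarray(weights, float), node_ids=ids,
                      node_constructs=constructs or ["A"] * p, fits=[])


class TestThresholdEdges:
    def test_two_value_mean_threshold(self):
        W = np.zeros((3, 3))
        W[0, 1] = 0.010
        W[1, 2] = 0.018
        edges = threshold_edges(make_result(W))
        assert edges.threshold == pytest.approx(0.014)
        assert [(e.source, e.target) for e in edges.edges] == [("N1", "N2")]

    def test_fixed_threshold_can_empty_the_list(self):
        W = np.zeros((3, 3))
        W[0, 1] = 0.012
        W[2, 0] = -0.010
        edges = threshold_edges(make_result(W), rule="fixed",
                                fixed_value=0.014)
        assert len(edges) == 0

    def test_edge_at_threshold_is_retained(self):
        W = np.zeros((3, 3))
        W[0, 1] = 0.014
        edges = threshold_edges(make_result(W), rule="fixed",
                                fixed_value=0.014)
        assert len(edges) == 1

    def test_autoregressive_only_matrix_gives_empty_list(self):
        W = np.diag([0.3, 0.2, 0.4])
        with pytest.warns(RuntimeWarning, match="no nonzero"):
            edges = threshold_edges(make_result(W))
        assert len(edges) == 0
        assert len(edges.autoregressive) == 3

    def test_signed_mean_rule(self):
        W = np.zeros((3, 3))
        W[0, 1] = 0.03
        W[1, 0] = -0.01
        edges = threshold_edges(make_result(W),
                                rule="mean_signed_crosslagged")
        assert edges.threshold == pytest.approx(0.01)
        assert len(edges) == 2  # |−0.01| >= 0.01 retained too


class TestSummarizeEdges:
    def test_published_share_arithmetic(self):
        # 194 positive of 223 nonzero cross-lagged edges -> 87%
        p = 16
        W = np.zeros((p, p))
        off = [(i, j) for i in range(p) for j in range(p) if i != j]
        for k, (i, j) in enumerate(off[:223]):
            W[i, j] = 0.02 if k < 194 else -0.02
        edges = threshold_edges(make_result(W), rule="fixed", fixed_value=0.0)
        s = summarize_edges(edges)
        assert s["n_edges"] == 223
        assert s["n_positive"] == 194
        assert s["percent_positive"] == 87

    def test_all_positive(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[0, 2] = W[1, 2] = W[2, 1] = 0.05
        s = summarize_edges(threshold_edges(make_result(W), rule="fixed",
                                            fixed_value=0.0))
        assert s["percent_positive"] == 100

    def test_tie_broken_lexicographically(self):
        W = np.zeros((3, 3))
        W[2, 1] = 0.3
        W[0, 1] = -0.3
        s = summarize_edges(threshold_edges(make_result(W), rule="fixed",
                                            fixed_value=0.0))
        assert s["percent_positive"] == 50
        top = s["top_edges"]
        assert (top[0].source, top[0].target) == ("N0", "N1")
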