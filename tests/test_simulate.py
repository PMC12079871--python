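"""Synthetic two-wave generator, recovery metrics, and power machinery."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from clpnet.config import AnalysisConfig
from clpnet.estimation import estimate_clpn
from clpnet.preprocess import transform_dataset
from clpnet.simulate import (SyntheticSpec, default_spec, generate_panel,
                             make_true_b, power_analysis, recovery_metrics)

from conftest import small_nodes, strong_spec


class TestGeneratePanel:
    def test_same_spec_and_seed_identical(self):
        spec = default_spec(n_subjects=200, seed=3)
        a = generate_panel(spec, seed=5)
        b = generate_panel(spec, seed=5)
        np.testing.assert_array_equal(a.wave1, b.wave1)
        np.testing.assert_array_equal(a.wave2, b.wave2)

    def test_responses_within_declared_ranges(self):
        spec = default_spec(n_subjects=500, seed=1)
        ds = generate_panel(spec, seed=2)
        ds.validate()  # range contract enforced by the validator
        for j, nd in enumerate(ds.nodes):
            assert ds.wave1[:, j].min() >= nd.response_min
            assert ds.wave2[:, j].max() <= nd.response_max

    def test_null_model_cross_construct_correlations_small(self):
        nodes = small_nodes(2, 2)
        spec = SyntheticSpec(n_subjects=5000, nodes=nodes,
                             true_b=np.zeros((4, 4)), r_between=0.0)
        ds = generate_panel(spec, seed=4)
        ga = [j for j, nd in enumerate(ds.nodes) if nd.construct == "GA"]
        iu = [j for j, nd in enumerate(ds.nodes) if nd.construct == "IU"]
        for i in ga:
            for j in iu:
                r = np.corrcoef(ds.wave1[:, i], ds.wave2[:, j])[0, 1]
                assert abs(r) < 0.05

    def test_anxiety_items_right_skewed(self):
        spec = default_spec(n_subjects=5000, seed=6)
        ds = generate_panel(spec, seed=7)
        for j, nd in enumerate(ds.nodes):
            if nd.construct == "GA":
                assert stats.skew(ds.wave1[:, j], bias=False) > 0.5

    def test_latent_regression_recovers_true_b(self):
        spec = default_spec(n_subjects=5000, seed=8)
        ds, z1, z2 = generate_panel(spec, seed=9, return_latents=True)
        p = z1.shape[1]
        Z = np.column_stack([np.ones(len(z1)), z1])
        for j in range(p):
            beta, res_ss, *_ = np.linalg.lstsq(Z, z2[:, j], rcond=None)
            # standard errors from the OLS covariance
            sigma2 = res_ss[0] / (len(z1) - p - 1)
            cov = sigma2 * np.linalg.inv(Z.T @ Z)
            se = np.sqrt(np.diag(cov))[1:]
            # 4-SE simultaneous bound: 361 coefficients are tested at once,
            # so a per-coefficient 2-SE band would fail by design
            np.testing.assert_array_less(
                np.abs(beta[1:] - spec.true_b[:, j]), 4.0 * se + 1e-9)

    def test_non_positive_definite_correlation_rejected(self):
        nodes = small_nodes(3, 3)
        spec = SyntheticSpec(n_subjects=100, nodes=nodes,
                             true_b=np.zeros((6, 6)), r_within=-0.9,
                             r_between=0.0)
        with pytest.raises(ValueError, match="positive definite"):
            generate_panel(spec, seed=1)

    def test_covariate_effects_shift_wave2(self):
        nodes = small_nodes(1, 1)
        G = np.array([[2.0, 0.0]])
        spec = SyntheticSpec(n_subjects=4000, nodes=nodes,
                             true_b=np.zeros((2, 2)), n_covariates=1,
                             covariate_effects=G)
        ds = generate_panel(spec, seed=3)
        r = np.corrcoef(ds.covariates[:, 0], ds.wave2[:, 0])[0, 1]
        assert r > 0.5
        r2 = np.corrcoef(ds.covariates[:, 0], ds.wave2[:, 1])[0, 1]
        assert abs(r2) < 0.05

    def test_bad_threshold_spec_rejected(self):
        nodes = small_nodes(1, 1)
        with pytest.raises(ValueError, match="thresholds|cut points"):
            SyntheticSpec(n_subjects=10, nodes=nodes,
                          true_b=np.zeros((2, 2)),
                          likert_thresholds={"GA": (0.5,)})


class TestRecoveryMetrics:
    def test_perfect_estimate(self):
        B = make_true_b(5, ["A"] * 5, density=0.3, seed=1)
        rm = recovery_metrics(B, B)
        assert (rm.sensitivity, rm.specificity, rm.weight_correlation) == \
            (1.0, 1.0, 1.0)

    def test_all_zero_estimate(self):
        B = make_true_b(5, ["A"] * 5, density=0.3, seed=2)
        rm = recovery_metrics(B, np.zeros_like(B))
        assert rm.sensitivity == 0.0
        assert rm.specificity == 1.0
        assert rm.degenerate

    def test_hand_built_half_recovery(self):
        p = 6
        true = np.zeros((p, p))
        cells = [(0, 1), (0, 2), (1, 3), (2, 4), (3, 5), (4, 0), (5, 1),
                 (1, 0), (2, 3), (3, 4)]
        for i, j in cells:
            true[i, j] = 0.2
        est = np.zeros((p, p))
        for i, j in cells[:5]:
            est[i, j] = 0.2
        rm = recovery_metrics(true, est)
        assert rm.sensitivity == pytest.approx(0.5)
        assert rm.specificity == pytest.approx(1.0)

    def test_no_true_edges_sensitivity_undefined(self):
        true = np.eye(4) * 0.3
        est = np.zeros((4, 4))
        with pytest.warns(RuntimeWarning, match="sensitivity undefined"):
            rm = recovery_metrics(true, est)
        assert np.isnan(rm.sensitivity)
        assert rm.specificity == 1.0


class TestPowerAnalysis:
    def test_oracle_injection_gives_perfect_metrics(self):
        # harness check: scoring the generating matrix itself is perfect
        B = make_true_b(4, ["A"] * 4, density=0.4, seed=3)
        rm = recovery_metrics(B, B, threshold_rule=None)
        assert min(rm.sensitivity, rm.specificity,
                   rm.weight_correlation) == 1.0

    def test_sensitivity_improves_with_sample_size(self):
        spec = strong_spec(0, p_per_construct=3, weights=(0.15, 0.25),
                           seed=5)
        cfg = AnalysisConfig(cv_folds=5, lambda_grid_size=30)
        curve = power_analysis(spec, [150, 1200], replications=3, seed=5,
                               config=cfg)
        assert curve.mean["sensitivity"][1200] >= \
            curve.mean["sensitivity"][150]
        frame = curve.to_frame()
        assert set(frame["metric"]) == {"sensitivity", "specificity",
                                        "weight_correlation"}

    def test_grid_must_increase(self):
        spec = strong_spec(100, seed=1)
        with pytest.raises(ValueError):
            power_analysis(spec, [500, 250], replications=1)

    def test_deterministic_given_seed(self):
        spec = strong_spec(0, p_per_construct=2, seed=2)
        cfg = AnalysisConfig(cv_folds=4, lambda_grid_size=20)
        a = power_analysis(spec, [200], replications=2, seed=9, config=cfg)
        b = power_analysis(spec, [200], replications=2, seed=9, config=cfg)
        assert a.mean == b.mean and a.sd == b.sd


class TestDiscretizationEffect:
    def test_ordinal_pipeline_close_to_latent_pipeline(self):
        """Discretization attenuates but does not destroy weight recovery."""
        corr_ord, corr_lat = [], []
        cfg = AnalysisConfig(cv_folds=5, lambda_grid_size=30)
        spec = default_spec(n_subjects=5000, seed=10)
        for rep in range(2):
            ds, z1, z2 = generate_panel(spec, seed=30 + rep,
                                        return_latents=True)
            res_o = estimate_clpn(transform_dataset(ds),
                                  dataclasses.replace(cfg, seed=rep))
            lat = dataclasses.replace(ds, wave1=z1, wave2=z2,
                                      transformed=True)
            res_l = estimate_clpn(lat, dataclasses.replace(cfg, seed=rep))
            corr_ord.append(recovery_metrics(
                spec.true_b, res_o).weight_correlation)
            corr_lat.append(recovery_metrics(
                spec.true_b, res_l).weight_correlation)
        assert np.mean(corr_ord) >= 0.8 * np.mean(corr_lat)


class TestSpecSerialization:
    def test_yaml_round_trip_preserves_generated_data(self, tmp_path):
        from clpnet.simulate import load_spec, save_spec
        spec = default_spec(n_subjects=80, seed=11)
        path = tmp_path / "spec.yaml"
        save_spec(spec, path)
        loaded = load_spec(path)
        np.testing.assert_array_equal(spec.true_b, loaded.true_b)
        a = generate_panel(spec, seed=12)
        b = generate_panel(loaded, seed=12)
        np.testing.assert_array_equal(a.wave1, b.wave1)
        np.testing.assert_array_equal(a.wave2, b.wave2)
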