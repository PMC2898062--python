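import math

import numpy as np
import pytest
import statsmodels.api as sm

from readpref.context import ContextConfig, build_training_set
from readpref.countdata import GeneCounts
from readpref.poislin import (
    fit_linear_pref,
    fit_offset_glm,
    load_linear_model,
    null_deviance,
    poisson_deviance,
    predict_gene_log_pref,
    predict_log_pref,
    save_linear_model,
    update_expression,
)
from readpref.simulate import LinearPreference, SimConfig, simulate_dataset

from .conftest import make_gene


class TestPoissonDeviance:
    def test_saturated_fit_is_zero(self):
        assert poisson_deviance([3, 1, 4], [3, 1, 4]) == 0.0

    def test_closed_form_single_count(self):
        assert poisson_deviance([2], [1]) == pytest.approx(2 * (2 * math.log(2) - 1))

    def test_zero_count_branch(self):
        assert poisson_deviance([0], [1]) == pytest.approx(2.0)

    def test_nonpositive_mu_rejected(self):
        with pytest.raises(ValueError):
            poisson_deviance([1], [0.0])


class TestNullDeviance:
    def test_uniform_counts_fit_exactly(self):
        g = make_gene("g", "ACGTACG", [3, 3, 3], flank=2)
        assert null_deviance([g]) == 0.0

    def test_hand_evaluation(self):
        g = make_gene("g", "ACGTAC", [0, 2], flank=2)
        expected = 2 * (1 + (2 * math.log(2) - 1))
        assert null_deviance([g]) == pytest.approx(expected)

    def test_additive_over_genes(self):
        g1 = make_gene("a", "ACGTAC", [0, 2], flank=2)
        g2 = make_gene("b", "ACGTACG", [1, 5, 0], flank=2)
        assert null_deviance([g1, g2]) == pytest.approx(
            null_deviance([g1]) + null_deviance([g2])
        )

    def test_zero_read_gene_contributes_nothing(self):
        g = make_gene("z", "ACGTAC", [0, 0], flank=2)
        assert null_deviance([g]) == 0.0


class TestFitOffsetGlm:
    def test_all_reference_windows_closed_form_intercept(self):
        # all-T windows encode to zeros: alpha = log(sum n / sum e^nu)
        g = GeneCounts("t", "T" * 30, 5, 25, np.arange(20))
        ts = build_training_set([g], ContextConfig(2, 2))
        rng = np.random.default_rng(1)
        ts.offsets = rng.normal(0, 0.5, ts.n_rows)
        fit = fit_offset_glm(ts)
        expected = math.log(ts.y.sum() / np.exp(ts.offsets).sum())
        assert fit.alpha == pytest.approx(expected, rel=1e-8)
        assert np.allclose(fit.beta, 0.0, atol=1e-6)

    def test_weights_equal_replication(self, small_dataset):
        genes, _ = small_dataset
        ts = build_training_set(genes[:3], ContextConfig(2, 2))
        doubled = build_training_set(genes[:3], ContextConfig(2, 2))
        doubled.weights = np.full(ts.n_rows, 2.0)
        replicated = build_training_set(genes[:3] * 2, ContextConfig(2, 2))
        fit_w = fit_offset_glm(doubled)
        fit_r = fit_offset_glm(replicated)
        assert fit_w.alpha == pytest.approx(fit_r.alpha, rel=1e-8)
        assert np.allclose(fit_w.beta, fit_r.beta, rtol=1e-6, atol=1e-9)


class TestUpdateExpression:
    def test_uniform_preference_limit(self):
        g = make_gene("g", "ACGTACGTAC", [1, 2, 3, 4, 5, 3], flank=2)
        cfg = ContextConfig(1, 1)
        nu = update_expression([g], 0.0, np.zeros(6), cfg)
        assert nu[0] == pytest.approx(math.log(18 / 6))

    def test_fitted_totals_match_observed(self, small_dataset):
        genes, _ = small_dataset
        cfg = ContextConfig(2, 2)
        rng = np.random.default_rng(3)
        beta = rng.normal(0, 0.2, 3 * cfg.K)
        nu = update_expression(genes, 0.1, beta, cfg)
        for g, v in zip(genes, nu):
            ts = build_training_set([g], cfg)
            mu = np.exp(v + 0.1 + ts.X @ beta)
            assert mu.sum() == pytest.approx(g.N, rel=1e-12)

    def test_doubling_counts_shifts_nu_by_log2(self):
        g = make_gene("g", "ACGTACGTAC", [1, 2, 3, 4, 5, 3], flank=2)
        g2 = make_gene("g", "ACGTACGTAC", [2, 4, 6, 8, 10, 6], flank=2)
        cfg = ContextConfig(1, 1)
        beta = np.arange(6) * 0.1
        nu1 = update_expression([g], 0.0, beta, cfg)
        nu2 = update_expression([g2], 0.0, beta, cfg)
        assert nu2[0] - nu1[0] == pytest.approx(math.log(2))

    def test_zero_read_gene_gets_sentinel(self):
        g = make_gene("z", "ACGTAC", [0, 0], flank=2)
        nu = update_expression([g], 0.0, np.zeros(6), ContextConfig(1, 1))
        assert nu[0] == -np.inf


class TestFitLinearPref:
    def test_no_signal_r2_near_zero(self):
        sim = SimConfig(
            n_genes=100,
            region_length_range=(1000, 1000),
            flank_length=5,
            seed=17,
        )
        genes, _ = simulate_dataset(sim)
        model = fit_linear_pref(genes, ContextConfig(3, 3))
        assert abs(model.diagnostics.r2) < 0.01

    def test_deviance_trajectory_non_increasing(self, small_dataset):
        genes, _ = small_dataset
        model = fit_linear_pref(genes, ContextConfig(3, 3), rel_tol=1e-6, max_iter=30)
        traj = model.diagnostics.deviance_trajectory
        assert (np.diff(traj) <= 1e-8 * traj[0]).all()

    def test_matches_joint_glm_with_gene_indicators(self, small_dataset):
        genes, _ = small_dataset
        genes = genes[:3]
        cfg = ContextConfig(2, 2)
        model = fit_linear_pref(genes, cfg, rel_tol=1e-12, max_iter=500)
        ts = build_training_set(genes, cfg)
        dummies = np.equal.outer(ts.gene_index, np.arange(len(genes))).astype(float)
        X = np.column_stack([dummies, ts.X])
        joint = sm.GLM(ts.y, X, family=sm.families.Poisson()).fit(
            maxiter=300, tol=1e-12
        )
        assert model.diagnostics.d == pytest.approx(joint.deviance, rel=1e-6)

    def test_r2_definition_and_bounds(self, small_dataset):
        genes, _ = small_dataset
        model = fit_linear_pref(genes, ContextConfig(3, 3))
        diag = model.diagnostics
        assert diag.r2 == pytest.approx(1 - diag.d / diag.d0, rel=1e-12)
        assert diag.r2 <= 1.0

    def test_parameter_recovery_single_seed(self, planted_linear):
        sim = SimConfig(
            n_genes=25,
            region_length_range=(400, 400),
            flank_length=10,
            preference_spec=planted_linear,
            seed=8,
        )
        genes, _ = simulate_dataset(sim)
        model = fit_linear_pref(genes, planted_linear.cfg, rel_tol=1e-4, max_iter=100)
        z = (model.beta - planted_linear.beta) / model.diagnostics.se
        assert np.mean(np.abs(z) < 3) >= 0.95


class TestPredictAndSerialize:
    def test_reference_window_predicts_alpha(self, small_dataset):
        genes, _ = small_dataset
        model = fit_linear_pref(genes, ContextConfig(2, 2))
        assert predict_log_pref(model, ["TTTT"])[0] == pytest.approx(model.alpha)

    def test_single_coefficient_difference(self, small_dataset):
        genes, _ = small_dataset
        model = fit_linear_pref(genes, ContextConfig(1, 2))
        # windows differ only at offset 0: T -> C
        d = predict_log_pref(model, ["TCT"])[0] - predict_log_pref(model, ["TTT"])[0]
        assert d == pytest.approx(model.coefficient(0, "C"), rel=1e-12)

    def test_serialization_round_trip_bit_exact(self, small_dataset, tmp_path):
        genes, _ = small_dataset
        model = fit_linear_pref(genes, ContextConfig(2, 2))
        path = tmp_path / "model.tsv"
        save_linear_model(model, path)
        loaded = load_linear_model(path)
        assert loaded.alpha == model.alpha
        assert (loaded.beta == model.beta).all()
        windows = ["ACGT", "TTTT", "GGCC"]
        assert (
            predict_log_pref(loaded, windows).tolist()
            == predict_log_pref(model, windows).tolist()
        )
        assert loaded.nu == model.nu

    def test_prediction_consistent_with_training_deviance(self, small_dataset):
        genes, _ = small_dataset
        cfg = ContextConfig(2, 2)
        model = fit_linear_pref(genes, cfg, rel_tol=1e-8, max_iter=100)
        d = 0.0
        for g in genes:
            a = predict_gene_log_pref(model, g)
            mu = np.exp(model.nu[g.gene_id] + a)
            d += poisson_deviance(g.counts, mu)
        assert d == pytest.approx(model.diagnostics.d, rel=1e-10)
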