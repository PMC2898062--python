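import math

import numpy as np
import pytest

from readpref.context import ContextConfig, build_training_set
from readpref.treepref import (
    BoostParams,
    assign_folds,
    build_boost_training_set,
    cv_r2,
    fit_boost,
    load_boost_model,
    make_targets,
    mle_expression,
    predict_gene_log_pref,
    predict_log_pref,
    predict_pref,
    save_boost_model,
)

from .conftest import make_gene

FAST = BoostParams(n_trees=200, seed=3)


class TestMakeTargets:
    def test_mean_equal_counts_give_zero_targets(self):
        g = make_gene("g", "ACGTACG", [2, 2, 2], flank=2)
        targets, weight = make_targets(g)
        assert targets.tolist() == [0.0, 0.0, 0.0]
        assert weight == pytest.approx(2.0)

    def test_zero_replacement_hand_evaluation(self):
        g = make_gene("g", "ACGTAC", [0, 4], flank=2)
        targets, weight = make_targets(g)
        assert targets == pytest.approx([math.log(0.25), math.log(2.0)])
        assert weight == pytest.approx(2.0)

    def test_doubling_counts_algebra(self):
        g1 = make_gene("g", "ACGTACG", [0, 2, 6], flank=2)
        g2 = make_gene("g", "ACGTACG", [0, 4, 12], flank=2)
        t1, _ = make_targets(g1)
        t2, _ = make_targets(g2)
        assert t2[1:] == pytest.approx(t1[1:])
        assert t2[0] - t1[0] == pytest.approx(-math.log(2))

    def test_no_read_gene_rejected(self):
        g = make_gene("z", "ACGTAC", [0, 0], flank=2)
        with pytest.raises(ValueError):
            make_targets(g)


class TestMleExpression:
    def test_uniform_preference_limit(self):
        assert mle_expression([2, 4, 6], [0, 0, 0]) == pytest.approx(math.log(12 / 3))

    def test_plug_in_evaluation(self):
        assert mle_expression([2, 4], [0.0, math.log(3)]) == pytest.approx(
            math.log(1.5)
        )

    def test_location_equivariance(self):
        a = np.array([0.3, -0.2, 1.0])
        n = [5, 1, 2]
        assert mle_expression(n, a + 0.7) == pytest.approx(mle_expression(n, a) - 0.7)

    def test_zero_total_gives_sentinel(self):
        assert mle_expression([0, 0], [0.1, 0.2]) == -np.inf

    def test_fitted_totals_identity(self):
        rng = np.random.default_rng(5)
        n = rng.poisson(4.0, 50)
        a = rng.normal(0, 0.5, 50)
        nu = mle_expression(n, a)
        assert np.exp(nu + a).sum() == pytest.approx(n.sum(), rel=1e-12)


class TestFitBoost:
    def _training_set(self, genes, cfg=ContextConfig(2, 2)):
        return build_boost_training_set(genes, cfg)

    def test_constant_targets_predict_constant(self, small_dataset):
        genes, _ = small_dataset
        ts = self._training_set(genes[:4])
        ts.targets = np.full(ts.n_rows, 1.25)
        model = fit_boost(ts, FAST)
        assert np.allclose(model.predict_encoded(ts.X), 1.25, atol=1e-6)

    def test_deterministic_under_seed(self, small_dataset):
        genes, _ = small_dataset
        ts = self._training_set(genes[:4])
        p1 = fit_boost(ts, FAST).predict_encoded(ts.X)
        p2 = fit_boost(ts, FAST).predict_encoded(ts.X)
        assert (p1 == p2).all()

    def test_planted_signal_heldout_recovery(self, small_dataset):
        genes, _ = small_dataset
        cfg = ContextConfig(1, 1)
        effect = {"A": 1.0, "C": -0.5, "G": 0.3, "T": 0.0}
        ts = self._training_set(genes[:8], cfg)
        first_base = [
            g.region_sequence[j] for g in genes[:8] if g.N > 0 for j in range(g.L)
        ]
        rng = np.random.default_rng(11)
        ts.targets = np.array([effect[b] for b in first_base]) + rng.normal(
            0, 0.05, ts.n_rows
        )
        model = fit_boost(ts, BoostParams(n_trees=500, seed=3))
        held = self._training_set(genes[8:], cfg)
        truth = np.array(
            [effect[g.region_sequence[j]] for g in genes[8:] if g.N > 0 for j in range(g.L)]
        )
        pred = model.predict_encoded(held.X)
        ss_res = ((pred - truth) ** 2).sum()
        ss_tot = ((truth - truth.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot >= 0.95

    def test_weight_replication_invariance(self, small_dataset):
        """k-fold row replication at weight w/k leaves the fit unchanged."""
        genes, _ = small_dataset
        cfg = ContextConfig(2, 2)
        params = BoostParams(
            n_trees=100, subsample_fraction=1.0, min_node_weight=0.0, seed=3
        )
        ts = self._training_set(genes[:3], cfg)
        rep = self._training_set([genes[0]] * 2 + genes[1:3], cfg)
        first_rows = genes[0].L
        rep.weights[: 2 * first_rows] /= 2.0
        rep.targets[:first_rows] = rep.targets[first_rows : 2 * first_rows] = ts.targets[
            :first_rows
        ]
        probe = self._training_set(genes[3:6], cfg).X
        p1 = fit_boost(ts, params).predict_encoded(probe)
        p2 = fit_boost(rep, params).predict_encoded(probe)
        assert np.allclose(p1, p2, rtol=1e-6, atol=1e-8)

    def test_agreement_with_windowwise_prediction(self, small_dataset):
        genes, _ = small_dataset
        cfg = ContextConfig(2, 2)
        ts = self._training_set(genes[:4], cfg)
        model = fit_boost(ts, FAST)
        g = genes[5]
        from readpref.context import extract_window

        windows = [
            extract_window(g.full_sequence, g.region_start, j, cfg)
            for j in range(g.L)
        ]
        assert np.allclose(
            predict_log_pref(model, windows), predict_gene_log_pref(model, g)
        )


class TestPredictPref:
    def test_normalized_mean_is_one(self, small_dataset):
        genes, _ = small_dataset
        ts = build_boost_training_set(genes[:4], ContextConfig(2, 2))
        model = fit_boost(ts, FAST)
        pref = predict_pref(model, genes[4], normalize=True)
        assert pref.mean() == pytest.approx(1.0, abs=1e-12)
        assert (pref > 0).all()


class TestCrossValidation:
    def test_fold_assignment_partitions_and_is_deterministic(self):
        ids = [f"g{i}" for i in range(17)]
        f1 = assign_folds(ids, 5, seed=4)
        f2 = assign_folds(list(reversed(ids)), 5, seed=4)
        assert f1 == f2
        sizes = np.bincount(list(f1.values()), minlength=5)
        assert sizes.sum() == 17 and sizes.max() - sizes.min() <= 1

    def test_pooled_r2_identity_and_order_invariance(self, small_dataset):
        genes, _ = small_dataset
        cfg = ContextConfig(2, 2)
        cv = cv_r2(genes, cfg, FAST, n_folds=5, seed=2)
        assert cv.cv_r2 == pytest.approx(1 - cv.d.sum() / cv.d0.sum(), abs=1e-12)
        shuffled = list(reversed(genes))
        cv2 = cv_r2(shuffled, cfg, FAST, n_folds=5, seed=2)
        assert cv2.cv_r2 == cv.cv_r2

    def test_too_few_genes_rejected(self, small_dataset):
        genes, _ = small_dataset
        with pytest.raises(ValueError):
            cv_r2(genes[:3], ContextConfig(2, 2), FAST, n_folds=5, seed=0)


class TestSerialization:
    def test_round_trip_predictions(self, small_dataset, tmp_path):
        genes, _ = small_dataset
        ts = build_boost_training_set(genes[:4], ContextConfig(2, 2))
        model = fit_boost(ts, FAST)
        path = tmp_path / "boost.json"
        save_boost_model(model, path)
        loaded = load_boost_model(path)
        assert loaded.params == model.params
        assert loaded.cfg == model.cfg
        assert np.allclose(
            loaded.predict_encoded(ts.X), model.predict_encoded(ts.X)
        )

    def test_wrong_format_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError):
            load_boost_model(p)
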