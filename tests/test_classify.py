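import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegrel import (
    ConfusionCounts,
    PsoConfig,
    SvmConfig,
    compute_metrics,
    cross_validate,
    knn_baseline,
    pso_tune,
    select_scenario,
)
from eegrel.classify import confusion_from_predictions, knn_fit_predict, make_svm
from eegrel.exceptions import ConfigError, OptimizationFailureError
from eegrel.features import ObservationMatrix


def _blobs(rng, n_per_class=30, dim=6, separation=20.0):
    a = rng.normal(size=(n_per_class, dim))
    b = rng.normal(size=(n_per_class, dim)) + separation
    X = np.vstack([a, b])
    y = np.array(["normal"] * n_per_class + ["ictal"] * n_per_class)
    return X, y


class TestMetrics:
    def test_perfect_classifier_scores_100_everywhere(self):
        m = compute_metrics(ConfusionCounts(n_tp=10, n_fn=0, n_tn=10, n_fp=0))
        assert (m.a_ac, m.a_se, m.a_sp) == (100.0, 100.0, 100.0)

    def test_worked_confusion_table(self):
        m = compute_metrics(ConfusionCounts(n_tp=9, n_fn=1, n_tn=8, n_fp=2))
        assert m.a_se == 90.0
        assert m.a_sp == 80.0
        assert m.a_ac == 85.0

    @settings(deadline=None, max_examples=100)
    @given(
        tp=st.integers(0, 50), fn=st.integers(0, 50),
        tn=st.integers(0, 50), fp=st.integers(0, 50),
    )
    def test_identities_hold_on_any_confusion_table(self, tp, fn, tn, fp):
        if tp + fn + tn + fp == 0:
            with pytest.raises(ConfigError):
                compute_metrics(ConfusionCounts(tp, fn, tn, fp))
            return
        m = compute_metrics(ConfusionCounts(tp, fn, tn, fp))
        assert m.a_ac == pytest.approx(100 * (tp + tn) / (tp + fn + tn + fp))
        if tp + fn:
            assert m.a_se == pytest.approx(100 * tp / (tp + fn))
        else:
            assert np.isnan(m.a_se)
        if tn + fp:
            assert m.a_sp == pytest.approx(100 * tn / (tn + fp))
        else:
            assert np.isnan(m.a_sp)

    def test_zero_denominator_warns_and_reports_nan(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            m = compute_metrics(ConfusionCounts(n_tp=0, n_fn=0, n_tn=5, n_fp=1))
        assert np.isnan(m.a_se)

    def test_multiclass_confusion_keeps_overall_accuracy(self):
        y_true = np.array(["normal", "interictal", "ictal", "ictal"])
        y_pred = np.array(["normal", "ictal", "ictal", "interictal"])
        c = confusion_from_predictions(y_true, y_pred, "ictal")
        assert (c.n_tp, c.n_fn, c.n_tn, c.n_fp) == (1, 1, 1, 1)
        assert (c.n_c, c.n_t) == (2, 4)


class TestPso:
    def test_recovers_interior_optimum(self):
        target = np.log10([1.0, 1.0])

        def objective(c, s):
            p = np.log10([c, s])
            return -float(np.sum((p - target) ** 2))

        cfg = PsoConfig(swarm_size=50, iterations=100, seed=3)
        c, s = pso_tune(objective, cfg)
        width_c = np.log10(cfg.bounds_c[1] / cfg.bounds_c[0])
        width_s = np.log10(cfg.bounds_sigma[1] / cfg.bounds_sigma[0])
        assert abs(np.log10(c) - target[0]) < 0.01 * width_c
        assert abs(np.log10(s) - target[1]) < 0.01 * width_s

    def test_beats_exhaustive_grid_lookup(self):
        rng = np.random.default_rng(11)
        grid_c = np.logspace(-2, 3, 5)
        grid_s = np.logspace(-2, 2, 5)
        table = rng.random((5, 5))

        def objective(c, s):
            i = int(np.argmin(np.abs(np.log10(grid_c) - np.log10(c))))
            j = int(np.argmin(np.abs(np.log10(grid_s) - np.log10(s))))
            return float(table[i, j])

        c, s = pso_tune(objective, PsoConfig(seed=4))
        assert objective(c, s) >= table.max() - 1e-12

    def test_deterministic_given_seed(self):
        objective = lambda c, s: -((np.log10(c) - 1) ** 2) - (np.log10(s) + 1) ** 2
        a = pso_tune(objective, PsoConfig(seed=9))
        b = pso_tune(objective, PsoConfig(seed=9))
        assert a == b

    def test_all_nan_objective_fails(self):
        with pytest.raises(OptimizationFailureError):
            pso_tune(lambda c, s: float("nan"), PsoConfig(swarm_size=5, iterations=2))


class TestCrossValidation:
    def test_separable_classes_reach_near_perfect_accuracy(self, rng):
        X, y = _blobs(rng)
        cfg = SvmConfig(c=10.0, sigma=5.0)  # dispersion on the blob scale
        metrics = cross_validate(X, y, config=cfg, reps=3, seed=0, tune=False)
        assert metrics.mean_accuracy >= 99.0
        assert metrics.std_accuracy == 0.0  # every repetition is perfect
        assert metrics.positive_label == "ictal"

    def test_tuned_svm_on_separable_classes(self, rng):
        X, y = _blobs(rng, n_per_class=20)
        cfg = SvmConfig(pso=PsoConfig(swarm_size=8, iterations=10))
        metrics = cross_validate(X, y, config=cfg, reps=2, seed=1, tune=True)
        assert metrics.mean_accuracy >= 99.0

    def test_shuffled_labels_score_at_chance(self, rng):
        X, y = _blobs(rng, n_per_class=25)
        y_shuffled = rng.permutation(y)
        metrics = cross_validate(
            X, y_shuffled, config=SvmConfig(c=10.0, sigma=5.0), reps=10, seed=2,
            tune=False,
        )
        assert 35.0 <= metrics.mean_accuracy <= 65.0

    def test_identical_seed_reproduces_metrics(self, rng):
        X, y = _blobs(rng, n_per_class=15)
        a = cross_validate(X, y, reps=4, seed=5, tune=False)
        b = cross_validate(X, y, reps=4, seed=5, tune=False)
        assert [m.a_ac for m in a.per_rep] == [m.a_ac for m in b.per_rep]

    def test_one_against_all_reduces_to_binary_with_two_classes(self, rng):
        X, y = _blobs(rng, n_per_class=15, separation=2.0)
        ova = make_svm(1.0, 1.0, one_against_all=True).fit(X, y)
        binary = make_svm(1.0, 1.0, one_against_all=False).fit(X, y)
        assert np.array_equal(ova.predict(X), binary.predict(X))

    def test_rejects_single_class_and_bad_fraction(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ConfigError):
            cross_validate(X, ["a"] * 10, tune=False)
        with pytest.raises(ConfigError):
            cross_validate(X, ["a"] * 5 + ["b"] * 5, train_fraction=1.5, tune=False)


class TestKnn:
    def test_nearest_neighbour_of_a_training_point_is_itself(self, rng):
        X, y = _blobs(rng, n_per_class=10, separation=1.0)
        assert np.array_equal(knn_fit_predict(X, y, X, k=1), y)

    def test_baseline_separates_blobs(self, rng):
        X, y = _blobs(rng, n_per_class=20)
        metrics = knn_baseline(X, y, k=3, reps=5, seed=0)
        assert metrics.mean_accuracy >= 95.0


class TestScenarios:
    def _om(self, rng):
        X = rng.normal(size=(4 * 2 * 3, 6))
        return ObservationMatrix(
            X=X, labels=list("aabbab"),
            band_names=["delta", "theta", "alpha", "beta"], n_M=2, n_frames=3,
        )

    def test_scenario_2_restricts_to_delta_theta(self, rng):
        om = self._om(rng)
        sub = select_scenario(om, 2)
        assert sub.band_names == ["delta", "theta"]
        assert sub.X.shape[0] == 2 * 2 * 3

    def test_scenario_follows_explicit_ranking(self, rng):
        om = self._om(rng)
        sub = select_scenario(om, 2, ranking=["alpha", "beta", "delta", "theta"])
        assert sub.band_names == ["alpha", "beta"]

    def test_invalid_scenario_rejected(self, rng):
        with pytest.raises(ConfigError):
            select_scenario(self._om(rng), 5)
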