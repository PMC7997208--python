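"""Class weighting, undersampling, metrics and the benchmark protocol."""

from fractions import Fraction

import numpy as np
import pytest

from mdrisk import (
    ExperimentConfig,
    MDRBenchmark,
    ModelSpec,
    class_weights,
    evaluate_metrics,
    undersample,
)
from mdrisk.benchmark import rank_auc, run_benchmark, tune_hyperparameters
from mdrisk.encoding import Dataset, FeatureMatrix
from mdrisk.learners import PerceptronClassifier


def _dataset(X, y, kinds=None) -> Dataset:
    X = np.asarray(X, dtype=float)
    kinds = kinds or ("numeric",) * X.shape[1]
    names = tuple(f"x{j}" for j in range(X.shape[1]))
    return Dataset(features=FeatureMatrix(X=X, names=names,
                                          kinds=tuple(kinds)),
                   y=np.asarray(y))


def _separable(n=400, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, 3)) + 3.0 * y[:, None]
    return _dataset(X, y)


class TestClassWeights:
    def test_balance_identity_exact(self):
        for n0, n1 in ((2743, 270), (10, 10), (3, 1), (999, 7)):
            w = class_weights(n0, n1)
            assert w.beta0 * n0 == w.beta1 * n1 == Fraction(n0 + n1, 2)

    def test_printed_cohort_counts(self):
        w = class_weights(2743, 270)
        assert float(w.beta0) == pytest.approx(0.5492, abs=5e-4)
        assert float(w.beta1) == pytest.approx(5.5796, abs=5e-4)

    def test_balanced_case_is_unweighted(self):
        w = class_weights(10, 10)
        assert w.beta0 == w.beta1 == 1

    def test_small_case_hand_arithmetic(self):
        w = class_weights(3, 1)
        assert w.beta0 == Fraction(2, 3)
        assert w.beta1 == 2

    def test_zero_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights(0, 5)


class TestUndersample:
    def test_imbalanced_becomes_exactly_balanced(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 270 + [0] * 2743)
        ds = _dataset(rng.normal(size=(3013, 2)), y)
        bal = undersample(ds, seed=1)
        assert int(bal.y.sum()) == 270
        assert len(bal.y) == 540

    def test_balanced_input_unchanged_multiset(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 25)
        ds = _dataset(rng.normal(size=(50, 2)), y)
        bal = undersample(ds, seed=0)
        assert sorted(map(tuple, bal.features.X)) == \
            sorted(map(tuple, ds.features.X))

    def test_different_seeds_different_subsets_same_sizes(self):
        rng = np.random.default_rng(2)
        y = np.array([1] * 30 + [0] * 300)
        ds = _dataset(rng.normal(size=(330, 1)), y)
        a = undersample(ds, seed=0)
        b = undersample(ds, seed=1)
        assert len(a.y) == len(b.y) == 60
        assert not np.array_equal(a.features.X, b.features.X)


class TestMetrics:
    def test_perfect_scores(self):
        y = np.array([1, 0, 1, 0, 1])
        m = evaluate_metrics(y, y.astype(float))
        assert (m.accuracy, m.sensitivity, m.specificity, m.auc) == \
            (1.0, 1.0, 1.0, 1.0)

    def test_constant_scores_give_half_auc(self):
        y = np.array([0, 1] * 10)
        m = evaluate_metrics(y, np.full(20, 0.5))
        assert m.auc == pytest.approx(0.5)

    def test_hand_enumerated_auc(self):
        # 4 positive-negative pairs: wins 3, losses 1 -> 0.75
        m = evaluate_metrics(np.array([1, 0, 1, 0]),
                             np.array([0.9, 0.8, 0.7, 0.1]))
        assert m.auc == pytest.approx(0.75)

    def test_single_class_warns_nan_auc(self):
        with pytest.warns(UserWarning, match="single class"):
            m = evaluate_metrics(np.ones(4), np.full(4, 0.7))
        assert np.isnan(m.auc)

    def test_rank_auc_matches_sklearn_with_ties(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.integers(0, 2, 60)
            if y.min() == y.max():
                continue
            s = rng.integers(0, 5, 60) / 4.0  # heavy ties
            assert rank_auc(y, s) == pytest.approx(roc_auc_score(y, s),
                                                   abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        assert rank_auc(y, s) == pytest.approx(
            rank_auc(y, np.exp(5 * s) / (1 + np.exp(5 * s))), abs=1e-12)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            evaluate_metrics(np.array([0, 1]), np.array([0.5, 1.5]))


class TestPerceptron:
    def test_slp_learns_separable_data(self):
        ds = _separable(seed=5)
        clf = PerceptronClassifier(learning_rate=0.1, epochs=300,
                                   random_state=0)
        clf.fit(ds.features.X, ds.y)
        assert (clf.predict(ds.features.X) == ds.y).mean() > 0.95

    def test_mlp_learns_xor(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(-1, 1, size=(400, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        clf = PerceptronClassifier(hidden_layer_sizes=(16,),
                                   learning_rate=0.05, epochs=800,
                                   random_state=0)
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.9

    def test_uniform_weights_equal_unweighted(self):
        ds = _separable(seed=7)
        a = PerceptronClassifier(epochs=100, random_state=1).fit(
            ds.features.X, ds.y)
        b = PerceptronClassifier(epochs=100, random_state=1).fit(
            ds.features.X, ds.y, sample_weight=np.full(len(ds.y), 3.0))
        np.testing.assert_allclose(a.coefs_[0], b.coefs_[0], atol=1e-10)


class TestTuning:
    def test_single_point_grid(self):
        ds = _separable()
        spec = ModelSpec("LR", {"C": [1.0]})
        cfg = ExperimentConfig(n_partitions=1, seed=0)
        mask = np.ones(3, dtype=bool)
        assert tune_hyperparameters(ds.features.X, ds.y, spec, cfg,
                                    "weighted_cost", mask, seed=0) == \
            {"C": 1.0}

    def test_duplicated_grid_point_first_occurrence_wins(self):
        ds = _separable()
        spec = ModelSpec("LR", {"C": [1.0, 1.0]})
        cfg = ExperimentConfig(n_partitions=1, seed=0)
        mask = np.ones(3, dtype=bool)
        best = tune_hyperparameters(ds.features.X, ds.y, spec, cfg,
                                    "weighted_cost", mask, seed=0)
        assert best == {"C": 1.0}

    def test_chosen_point_attains_maximal_cv_auc(self):
        # exhaustive re-evaluation oracle over the grid
        from sklearn.model_selection import StratifiedKFold
        from mdrisk.benchmark import _fit_and_score
        ds = _separable(n=300, seed=8)
        X, y = ds.features.X, ds.y
        spec = ModelSpec("LR", {"C": [0.01, 1.0, 100.0]})
        cfg = ExperimentConfig(seed=0)
        mask = np.ones(3, dtype=bool)
        best = tune_hyperparameters(X, y, spec, cfg, "weighted_cost", mask,
                                    seed=9)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=9)
        folds = list(skf.split(X, y))

        def cv_auc(p_idx, params):
            aucs = [_fit_and_score("LR", params, X[tr], y[tr], X[va], y[va],
                                   "weighted_cost", mask, True,
                                   seed=(9 + 1009 * p_idx + 31 * f) % 2**31,
                                   threshold=0.5).auc
                    for f, (tr, va) in enumerate(folds)]
            return float(np.mean(aucs))

        scores = [cv_auc(i, p) for i, p in enumerate(spec.points())]
        assert cv_auc(spec.points().index(best), best) == max(scores)

    def test_too_few_minority_for_folds_rejected(self):
        rng = np.random.default_rng(9)
        y = np.array([1] * 3 + [0] * 100)
        X = rng.normal(size=(103, 2))
        spec = ModelSpec("LR", {"C": [1.0]})
        cfg = ExperimentConfig(seed=0)
        with pytest.raises(ValueError, match="fold"):
            tune_hyperparameters(X, y, spec, cfg, "weighted_cost",
                                 np.ones(2, dtype=bool), seed=0)


class TestBenchmark:
    def test_single_partition_has_zero_sd(self):
        ds = _separable(n=300, seed=10)
        cfg = ExperimentConfig(n_partitions=1, seed=0,
                               balancing=("weighted_cost",))
        res = MDRBenchmark(ds, specs=[ModelSpec("LR", {"C": [1.0]})],
                           config=cfg).fit()
        assert (res.table.filter(like="_sd") == 0.0).all().all()

    def test_metrics_within_unit_interval(self):
        ds = _separable(n=300, seed=11)
        cfg = ExperimentConfig(n_partitions=3, seed=0)
        res = MDRBenchmark(ds, specs=[ModelSpec("DT", {"max_depth": [3],
                                                       "min_samples_split": [2],
                                                       "min_samples_leaf": [1]})],
                           config=cfg).fit()
        metrics = res.raw[["accuracy", "sensitivity", "specificity", "auc"]]
        assert ((metrics >= 0) & (metrics <= 1)).all().all()

    def test_benchmark_reproducible(self):
        ds = _separable(n=250, seed=12)
        cfg = ExperimentConfig(n_partitions=2, seed=4,
                               balancing=("undersampling",))
        specs = [ModelSpec("LR", {"C": [1.0, 10.0]})]
        a = run_benchmark(ds, specs, cfg)
        b = run_benchmark(ds, specs, cfg)
        assert a.raw.equals(b.raw)

    def test_strong_separation_yields_high_auc(self):
        ds = _separable(n=400, seed=13)
        cfg = ExperimentConfig(n_partitions=2, seed=0,
                               balancing=("weighted_cost",))
        res = MDRBenchmark(ds, specs=[ModelSpec("LR", {"C": [1.0]})],
                           config=cfg).fit()
        assert res.table["auc_mean"].iloc[0] >= 0.9

    def test_xgb_backend_supports_both_strategies(self):
        ds = _separable(n=300, seed=15)
        cfg = ExperimentConfig(n_partitions=1, seed=0)
        res = MDRBenchmark(ds, specs=[ModelSpec(
            "XGB", {"n_estimators": [20], "max_depth": [2],
                    "learning_rate": [0.3]})], config=cfg).fit()
        assert set(res.raw["balancing"]) == {"undersampling", "weighted_cost"}
        assert (res.raw["auc"] > 0.9).all()

    def test_summary_mirrors_table_rows(self):
        ds = _separable(n=250, seed=14)
        cfg = ExperimentConfig(n_partitions=1, seed=0)
        res = MDRBenchmark(ds, specs=[ModelSpec("LR", {"C": [1.0]})],
                           config=cfg).fit()
        text = res.summary()
        assert "LR" in text and "undersampling" in text and \
            "weighted_cost" in text
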