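"""Bootstrap feature-selection strategies and their union."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mdrisk import (
    BootstrapConfig,
    BootstrapSelector,
    bootstrap_feature_stats,
    ci_difference_selection,
    encode_one_hot,
    final_union_selection,
    generate_cohort,
    select_mutual_information,
    select_proportions_median,
)
from mdrisk.cohort import Cohort, null_generator_config
from mdrisk.encoding import Dataset, FeatureMatrix
from mdrisk.schema import CohortSchema, Variable
from mdrisk.selection import FeatureScore, SelectionResult


def _dataset(X, names, kinds, y) -> Dataset:
    return Dataset(features=FeatureMatrix(X=np.asarray(X, dtype=float),
                                          names=tuple(names),
                                          kinds=tuple(kinds)),
                   y=np.asarray(y))


@pytest.fixture(scope="module")
def strong_binary_dataset():
    """One strongly informative flag (0.6 vs 0.1) plus one null flag."""
    rng = np.random.default_rng(0)
    n1, n0 = 270, 2743
    y = np.array([1] * n1 + [0] * n0)
    strong = np.concatenate([(rng.random(n1) < 0.6),
                             (rng.random(n0) < 0.1)]).astype(float)
    null = (rng.random(n1 + n0) < 0.3).astype(float)
    return _dataset(np.column_stack([strong, null]), ("strong", "null"),
                    ("binary", "binary"), y)


class TestAveragedStats:
    def test_informative_feature_reaches_tiny_average_p(
            self, strong_binary_dataset):
        cfg = BootstrapConfig(R=50, seed=0)
        avg_p = bootstrap_feature_stats(strong_binary_dataset, "pvalue", cfg)
        assert avg_p["strong"] < 1e-3
        assert avg_p["null"] > 0.05

    def test_average_mi_ranks_informative_first(self, strong_binary_dataset):
        cfg = BootstrapConfig(R=50, seed=0)
        avg_mi = bootstrap_feature_stats(strong_binary_dataset, "mi", cfg)
        assert avg_mi["strong"] > avg_mi["null"] >= 0.0

    def test_deterministic_given_seed(self, strong_binary_dataset):
        cfg = BootstrapConfig(R=20, seed=11)
        a = bootstrap_feature_stats(strong_binary_dataset, "pvalue", cfg)
        b = bootstrap_feature_stats(strong_binary_dataset, "pvalue", cfg)
        assert a == b

    def test_selection_monotone_in_effect_size(self):
        # widening the class-proportion gap never removes a feature from
        # the averaged-p selected set (fixed seeds, shared nulls)
        rng = np.random.default_rng(4)
        n1, n0 = 270, 2743
        y = np.array([1] * n1 + [0] * n0)
        base = 0.15
        previous = set()
        for gap in (0.0, 0.04, 0.08, 0.16):
            rng_g = np.random.default_rng(7)  # same draws per gap level
            x = np.concatenate([
                rng_g.random(n1) < base + gap,
                rng_g.random(n0) < base]).astype(float)
            ds = _dataset(x[:, None], ("f",), ("binary",), y)
            avg_p = bootstrap_feature_stats(
                ds, "pvalue", BootstrapConfig(R=60, seed=1))
            selected = select_proportions_median(avg_p, 0.05).selected
            assert previous <= selected or not previous
            previous = selected
        assert previous == {"f"}


class TestThresholdSelections:
    def test_p_threshold(self):
        res = select_proportions_median({"a": 0.01, "b": 0.50}, 0.05)
        assert res.selected == {"a"}
        assert select_proportions_median({"a": 1.0, "b": 1.0},
                                         0.05).selected == frozenset()

    def test_tie_at_alpha_excluded(self):
        assert select_proportions_median({"a": 0.05}, 0.05).selected == \
            frozenset()

    def test_mi_top_k(self):
        scores = {"a": 0.3, "b": 0.2, "c": 0.1}
        assert select_mutual_information(scores, 0).selected == frozenset()
        assert select_mutual_information(scores, 3).selected == \
            {"a", "b", "c"}
        assert select_mutual_information(scores, 2).selected == {"a", "b"}

    def test_mi_ties_break_lexicographically(self):
        assert select_mutual_information({"b": 0.2, "a": 0.2, "c": 0.1},
                                         1).selected == {"a"}


class TestCiSelection:
    def test_constant_equal_feature_not_selected(self):
        y = np.array([1] * 30 + [0] * 120)
        ds = _dataset(np.ones((150, 1)), ("c",), ("binary",), y)
        res = ci_difference_selection(ds, BootstrapConfig(R=50, seed=0))
        lo, hi = res.score_of("c")
        assert (lo, hi) == (0.0, 0.0)
        assert res.selected == frozenset()

    def test_median_gap_selected_with_positive_interval(self):
        rng = np.random.default_rng(1)
        n1, n0 = 270, 2743
        y = np.array([1] * n1 + [0] * n0)
        x = np.concatenate([rng.normal(25, 7, n1), rng.normal(20, 7, n0)])
        ds = _dataset(x[:, None], ("score",), ("numeric",), y)
        res = ci_difference_selection(ds, BootstrapConfig(R=100, seed=0))
        lo, hi = res.score_of("score")
        assert lo > 0 and "score" in res.selected

    def test_zero_subsample_size_rejected(self, strong_binary_dataset):
        with pytest.raises(ValueError):
            BootstrapConfig(subsample_fraction=0.0).validate()


class TestUnion:
    def _result(self, method, scores, selected):
        return SelectionResult(
            method=method,
            scores=tuple(FeatureScore(n, method, s, n in selected)
                         for n, s in scores.items()),
            selected=frozenset(selected))

    def test_idempotent_on_identical_sets(self, strong_binary_dataset):
        scores = {"strong": 0.01, "null": 0.9}
        mi_scores = {"strong": 0.2, "null": 0.0}
        ci_scores = {"strong": (0.1, 0.2), "null": (-0.1, 0.1)}
        results = (self._result("prop_median_test", scores, {"strong"}),
                   self._result("mutual_information", mi_scores, {"strong"}),
                   self._result("ci_difference", ci_scores, {"strong"}))
        final = final_union_selection(results, strong_binary_dataset, 0.9)
        assert final.union == final.retained == {"strong"}

    def test_union_contains_each_method(self, strong_binary_dataset):
        res = BootstrapSelector(strong_binary_dataset,
                                BootstrapConfig(R=20, seed=0)).fit()
        for part in (res.proportions_median, res.mutual_info, res.ci):
            assert part.selected <= res.final.union

    def test_duplicate_columns_drop_one(self):
        rng = np.random.default_rng(2)
        y = np.array([1] * 50 + [0] * 200)
        x = np.concatenate([(rng.random(50) < 0.7),
                            (rng.random(200) < 0.2)]).astype(float)
        ds = _dataset(np.column_stack([x, x]), ("a", "b"),
                      ("binary", "binary"), y)
        res = BootstrapSelector(ds, BootstrapConfig(R=40, seed=0)).fit()
        assert res.final.union == {"a", "b"}
        assert len(res.final.retained) == 1

    def test_retained_untouched_when_threshold_above_one(
            self, strong_binary_dataset):
        cfg = BootstrapConfig(R=20, seed=0, corr_threshold=1.0 + 1e-9)
        res = BootstrapSelector(strong_binary_dataset, cfg).fit()
        assert res.final.retained == res.final.union

    def test_mismatched_namespaces_rejected(self, strong_binary_dataset):
        a = self._result("prop_median_test", {"x": 0.1}, set())
        b = self._result("mutual_information", {"y": 0.1}, set())
        c = self._result("ci_difference", {"x": (0, 0)}, set())
        with pytest.raises(ValueError, match="namespace"):
            final_union_selection((a, b, c), strong_binary_dataset, 0.9)


class TestFacade:
    def test_full_determinism_byte_identical(self, strong_binary_dataset):
        cfg = BootstrapConfig(R=25, seed=3)
        a = BootstrapSelector(strong_binary_dataset, cfg).fit().to_json()
        b = BootstrapSelector(strong_binary_dataset, cfg).fit().to_json()
        assert a == b

    def test_json_has_three_method_blocks_plus_union(
            self, strong_binary_dataset):
        res = BootstrapSelector(strong_binary_dataset,
                                BootstrapConfig(R=10, seed=0)).fit()
        payload = res.to_dict()
        assert set(payload) == {"prop_median_test", "mutual_information",
                                "ci_difference", "union"}

    def test_mi_top_k_defaults_to_test_based_count(self, strong_binary_dataset):
        res = BootstrapSelector(strong_binary_dataset,
                                BootstrapConfig(R=25, seed=0)).fit()
        assert len(res.mutual_info.selected) == \
            len(res.proportions_median.selected)
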