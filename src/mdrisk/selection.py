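"""Bootstrap feature selection: averaged tests, mutual information, CIs.

Three filter strategies score every design-matrix feature against the
binary MDR label, each wrapped in bootstrap resampling:

1. *Averaged test p-values* — for each of R class-stratified resamples
   (with replacement, preserving the 270/2743 imbalance) compute a
   two-proportion z test (binary features) or Mood's median test
   (numeric features); average the R p-values and select features with
   average p below the significance level alpha.
2. *Averaged mutual information* — same resampling scheme, plug-in MI in
   bits per resample; select the top-k features by average MI (k
   defaults to the size of the test-based selection).
3. *Confidence interval of differences* — draw per-class subsamples
   *without* replacement, compute the MDR-minus-non-MDR difference of
   proportions (binary) or medians (numeric), and select features whose
   percentile interval over the R differences excludes zero.

The final selection is the union of the three sets, followed by a
correlation screen: within-union pairs with |r| at or above a threshold
drop the member ranked worse on average across the three methods.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .encoding import Dataset
from .stats import (
    binary_mutual_information_vec,
    discretize_equal_frequency,
    moods_median_pvalue,
    two_proportion_pvalue_vec,
)

__all__ = [
    "BootstrapConfig",
    "FeatureScore",
    "SelectionResult",
    "FinalSelection",
    "bootstrap_feature_stats",
    "select_proportions_median",
    "select_mutual_information",
    "ci_difference_selection",
    "final_union_selection",
    "BootstrapSelector",
    "SelectionResults",
]

PROP_MEDIAN = "prop_median_test"
MUTUAL_INFO = "mutual_information"
CI_DIFFERENCE = "ci_difference"


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling and selection settings.

    ``subsample_fraction`` applies only to the CI strategy (per-class
    draws without replacement); 0.5 makes the subsampling spread match
    the sampling variability of the full-data statistic, giving the
    percentile interval near-nominal coverage.  ``mi_top_k=None`` means
    "as many as the test-based method selected".
    """

    R: int = 3000
    alpha: float = 0.05
    ci_level: float = 0.95
    subsample_fraction: float = 0.5
    mi_top_k: int | None = None
    n_bins: int = 10
    corr_threshold: float = 0.9
    ci_method: str = "normal"
    seed: int = 0

    def validate(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.mi_top_k is not None and self.mi_top_k < 0:
            raise ValueError("mi_top_k must be >= 0")
        if self.ci_method not in ("normal", "percentile"):
            raise ValueError("ci_method must be 'normal' or 'percentile'")


@dataclass(frozen=True)
class FeatureScore:
    name: str
    method: str
    score: float | tuple[float, float]
    selected: bool


@dataclass(frozen=True)
class SelectionResult:
    """Per-method scores plus the selected name set."""

    method: str
    scores: tuple[FeatureScore, ...]
    selected: frozenset[str]

    def __post_init__(self) -> None:
        names = {s.name for s in self.scores}
        if not self.selected <= names:
            raise ValueError("selected set is not a subset of scored features")

    def score_of(self, name: str):
        for s in self.scores:
            if s.name == name:
                return s.score
        raise KeyError(name)


@dataclass(frozen=True)
class FinalSelection:
    """Union of the per-method selections and the correlation screen log."""

    union: frozenset[str]
    pairs: tuple[tuple[str, str, float], ...]
    retained: frozenset[str]


def _class_split(dataset: Dataset):
    X = dataset.features.X
    y = np.asarray(dataset.y)
    kinds = np.array(dataset.features.kinds)
    bin_idx = np.flatnonzero(kinds == "binary")
    num_idx = np.flatnonzero(kinds == "numeric")
    X1, X0 = X[y == 1], X[y == 0]
    return X1, X0, bin_idx, num_idx


def bootstrap_feature_stats(dataset: Dataset, statistic: str,
                            config: BootstrapConfig) -> dict[str, float]:
    """Per-feature score averaged over R class-stratified resamples.

    ``statistic='pvalue'`` dispatches the two-proportion test to binary
    features and Mood's median test to numeric ones; ``statistic='mi'``
    computes plug-in mutual information (bits) for every feature, with
    numeric features discretized into equal-frequency bins inside each
    resample.  Degenerate resamples contribute the convention values
    (p = 1 / MI = 0).  Deterministic given ``config.seed``.
    """
    config.validate()
    if statistic not in ("pvalue", "mi"):
        raise ValueError("statistic must be 'pvalue' or 'mi'")
    X1, X0, bin_idx, num_idx = _class_split(dataset)
    n1, n0 = len(X1), len(X0)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    names = dataset.features.names
    stage = 0 if statistic == "pvalue" else 1
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, stage]))
    total = np.zeros(len(names))
    X1b, X0b = X1[:, bin_idx], X0[:, bin_idx]
    labels = np.concatenate([np.ones(n1, dtype=int), np.zeros(n0, dtype=int)])
    for _ in range(config.R):
        i1 = rng.integers(0, n1, size=n1)
        i0 = rng.integers(0, n0, size=n0)
        k1 = X1b[i1].sum(axis=0)
        k0 = X0b[i0].sum(axis=0)
        if statistic == "pvalue":
            total[bin_idx] += two_proportion_pvalue_vec(k1, n1, k0, n0)
            for j in num_idx:
                vals = np.concatenate([X1[i1, j], X0[i0, j]])
                total[j] += moods_median_pvalue(vals, labels)
        else:
            total[bin_idx] += binary_mutual_information_vec(k1, n1, k0, n0)
            for j in num_idx:
                vals = np.concatenate([X1[i1, j], X0[i0, j]])
                x = discretize_equal_frequency(vals, config.n_bins)
                total[j] += _discrete_mi_bits(x, labels)
    total /= config.R
    return dict(zip(names, total))


def _discrete_mi_bits(x: np.ndarray, y: np.ndarray) -> float:
    joint = np.zeros((int(x.max()) + 1, 2))
    np.add.at(joint, (x, y), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    terms[~np.isfinite(terms)] = 0.0
    return max(float(terms.sum()), 0.0)


def select_proportions_median(avg_p: dict[str, float],
                              alpha: float = 0.05) -> SelectionResult:
    """Select features with averaged p-value strictly below alpha."""
    scores = tuple(
        FeatureScore(name, PROP_MEDIAN, float(p), bool(p < alpha))
        for name, p in avg_p.items())
    return SelectionResult(
        method=PROP_MEDIAN, scores=scores,
        selected=frozenset(s.name for s in scores if s.selected))


def select_mutual_information(avg_mi: dict[str, float],
                              k: int) -> SelectionResult:
    """Select the top-k features by averaged MI.

    Ties at the k-th value are broken by lexicographic feature name.
    """
    if k > len(avg_mi):
        raise ValueError("k exceeds the number of features")
    ranked = sorted(avg_mi, key=lambda n: (-avg_mi[n], n))
    chosen = frozenset(ranked[:k])
    scores = tuple(
        FeatureScore(name, MUTUAL_INFO, float(mi), name in chosen)
        for name, mi in avg_mi.items())
    return SelectionResult(method=MUTUAL_INFO, scores=scores, selected=chosen)


def ci_difference_selection(dataset: Dataset,
                            config: BootstrapConfig) -> SelectionResult:
    """Percentile-CI selection on MDR-minus-non-MDR differences.

    For each of R rounds, per-class subsamples of size
    ceil(subsample_fraction * n_c) are drawn without replacement; the
    difference of proportions (binary) or of medians (numeric) between
    the MDR and non-MDR subsamples is recorded.  A feature is selected
    when the central ``ci_level`` interval of its R differences excludes
    zero.  The default interval is the bootstrap standard-error (normal
    theory) interval, mean +- z * SD of the R differences: its endpoints
    are stable in R, so the null false-selection rate stays near
    1 - ci_level even at a few hundred resamples, where raw percentile
    endpoints are noisy enough to inflate it.  ``ci_method='percentile'``
    selects the plain percentile interval instead.
    """
    config.validate()
    X1, X0, bin_idx, num_idx = _class_split(dataset)
    n1, n0 = len(X1), len(X0)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    m1 = math.ceil(config.subsample_fraction * n1)
    m0 = math.ceil(config.subsample_fraction * n0)
    if m1 == 0 or m0 == 0:
        raise ValueError("subsample size is zero; increase subsample_fraction")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    names = dataset.features.names
    deltas = np.empty((config.R, len(names)))
    for r in range(config.R):
        i1 = rng.permutation(n1)[:m1]
        i0 = rng.permutation(n0)[:m0]
        deltas[r, bin_idx] = X1[i1][:, bin_idx].mean(axis=0) - \
            X0[i0][:, bin_idx].mean(axis=0)
        if len(num_idx):
            deltas[r, num_idx] = np.median(X1[i1][:, num_idx], axis=0) - \
                np.median(X0[i0][:, num_idx], axis=0)
    tail = (1.0 - config.ci_level) / 2.0
    if config.ci_method == "percentile":
        lo = np.quantile(deltas, tail, axis=0)
        hi = np.quantile(deltas, 1.0 - tail, axis=0)
    else:
        z = sps.norm.ppf(1.0 - tail)
        center = deltas.mean(axis=0)
        spread = deltas.std(axis=0, ddof=1) if config.R > 1 \
            else np.zeros(deltas.shape[1])
        lo, hi = center - z * spread, center + z * spread
    scores = []
    for j, name in enumerate(names):
        selected = bool(lo[j] > 0.0 or hi[j] < 0.0)
        scores.append(FeatureScore(name, CI_DIFFERENCE,
                                   (float(lo[j]), float(hi[j])), selected))
    return SelectionResult(
        method=CI_DIFFERENCE, scores=tuple(scores),
        selected=frozenset(s.name for s in scores if s.selected))


def _method_ranks(result: SelectionResult) -> dict[str, float]:
    """Rank features within one method, 1 = most informative."""
    names = [s.name for s in result.scores]
    if result.method == PROP_MEDIAN:
        key = np.array([s.score for s in result.scores])          # low p best
    elif result.method == MUTUAL_INFO:
        key = -np.array([s.score for s in result.scores])         # high MI best
    else:  # CI: distance of the interval from zero, larger is better
        key = -np.array([max(s.score[0], 0.0) - min(s.score[1], 0.0)
                         for s in result.scores])
    ranks = sps.rankdata(key, method="average")
    return dict(zip(names, ranks))


def final_union_selection(results, dataset: Dataset,
                          corr_threshold: float = 0.9) -> FinalSelection:
    """Union of the per-method selections plus a redundancy screen.

    All pairwise correlations within the union are examined — Pearson
    for numeric-numeric pairs, Spearman otherwise.  For each pair with
    |r| at or above ``corr_threshold`` (strongest first), the member
    with the worse (larger) average rank across the three methods is
    dropped.  Every examined pair is reported.
    """
    namespaces = {frozenset(s.name for s in r.scores) for r in results}
    if len(namespaces) != 1:
        raise ValueError("selection results do not share a feature namespace")
    union = frozenset().union(*(r.selected for r in results))
    rank_maps = [_method_ranks(r) for r in results]
    avg_rank = {n: float(np.mean([m[n] for m in rank_maps])) for n in union}

    kinds = dict(zip(dataset.features.names, dataset.features.kinds))
    ordered = [n for n in dataset.features.names if n in union]
    pairs: list[tuple[str, str, float]] = []
    for i, a in enumerate(ordered):
        xa = dataset.features.column(a)
        for b in ordered[i + 1:]:
            xb = dataset.features.column(b)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                r = 0.0
            elif kinds[a] == "numeric" and kinds[b] == "numeric":
                r = float(sps.pearsonr(xa, xb).statistic)
            else:
                r = float(sps.spearmanr(xa, xb).statistic)
            pairs.append((a, b, 0.0 if np.isnan(r) else r))

    retained = set(union)
    for a, b, r in sorted(pairs, key=lambda t: -abs(t[2])):
        if abs(r) < corr_threshold:
            break
        if a in retained and b in retained:
            retained.discard(a if avg_rank[a] > avg_rank[b] else b)
    return FinalSelection(union=union, pairs=tuple(pairs),
                          retained=frozenset(retained))


# -- model/results facade -----------------------------------------------------

class BootstrapSelector:
    """Bootstrap feature-selection model over an encoded dataset.

    Runs the three strategies and their union in one :meth:`fit` call::

        sel = BootstrapSelector(dataset, BootstrapConfig(R=200, seed=0))
        res = sel.fit()
        print(res.summary())
    """

    def __init__(self, dataset: Dataset, config: BootstrapConfig | None = None):
        self.dataset = dataset
        self.config = config or BootstrapConfig()
        self.config.validate()

    def fit(self) -> "SelectionResults":
        cfg = self.config
        avg_p = bootstrap_feature_stats(self.dataset, "pvalue", cfg)
        prop = select_proportions_median(avg_p, cfg.alpha)
        avg_mi = bootstrap_feature_stats(self.dataset, "mi", cfg)
        k = cfg.mi_top_k if cfg.mi_top_k is not None else len(prop.selected)
        mi = select_mutual_information(avg_mi, k)
        ci = ci_difference_selection(self.dataset, cfg)
        final = final_union_selection((prop, mi, ci), self.dataset,
                                      cfg.corr_threshold)
        return SelectionResults(self.dataset, cfg, prop, mi, ci, final)


@dataclass(frozen=True)
class SelectionResults:
    """Fitted selection: per-method results plus the final union."""

    dataset: Dataset
    config: BootstrapConfig
    proportions_median: SelectionResult
    mutual_info: SelectionResult
    ci: SelectionResult
    final: FinalSelection

    @property
    def selected_features(self) -> list[str]:
        """Final retained features in design-matrix column order."""
        return [n for n in self.dataset.features.names
                if n in self.final.retained]

    def summary(self) -> str:
        lines = ["Bootstrap feature selection"
                 f" (R={self.config.R}, alpha={self.config.alpha},"
                 f" ci_level={self.config.ci_level})", ""]
        for res in (self.proportions_median, self.mutual_info, self.ci):
            lines.append(f"{res.method}: {len(res.selected)} selected")
        lines.append(f"union: {len(self.final.union)} features; "
                     f"retained after correlation screen: "
                     f"{len(self.final.retained)}")
        lines.append("")
        lines.append("retained features:")
        for name in self.selected_features:
            lines.append(f"  {name}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def block(res: SelectionResult) -> list[dict]:
            return [{"feature": s.name, "score": s.score,
                     "selected": s.selected} for s in res.scores]

        return {
            PROP_MEDIAN: block(self.proportions_median),
            MUTUAL_INFO: block(self.mutual_info),
            CI_DIFFERENCE: block(self.ci),
            "union": {
                "features": sorted(self.final.union),
                "correlation_pairs": [
                    {"a": a, "b": b, "r": r} for a, b, r in self.final.pairs],
                "retained": sorted(self.final.retained),
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)
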