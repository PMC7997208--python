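"""Elementary two-sample statistics used by the feature-selection layer.

Three primitives, dispatched by feature kind:

* two-sample test of proportions (pooled-variance z) for binary features,
* Mood's median test (2x2 above/not-above grand median, Pearson chi^2
  with 1 df) for numeric features,
* plug-in mutual information with the binary class label, in bits.

Degenerate inputs follow explicit conventions rather than raising:
a pooled proportion of 0 or 1 (no variance) yields p = 1; an all-constant
numeric vector yields p = 1 through the degenerate contingency table; a
single-class label vector yields MI = 0 (H(Y) = 0) with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = [
    "two_proportion_pvalue",
    "two_proportion_pvalue_vec",
    "moods_median_pvalue",
    "mutual_information",
    "binary_mutual_information_vec",
    "discretize_equal_frequency",
]


def two_proportion_pvalue(k1: int, n1: int, k0: int, n0: int) -> float:
    """Two-sided p-value for H0: p1 = p0 from a pooled-variance z statistic.

    ``k1``/``n1`` are the active count and size in the positive (MDR)
    class, ``k0``/``n0`` in the negative class.  A pooled proportion of
    0 or 1 leaves the statistic undefined (zero variance); by convention
    this returns p = 1 (no evidence of a difference).
    """
    if not (0 <= k1 <= n1 and 0 <= k0 <= n0):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if n1 < 1 or n0 < 1:
        raise ValueError("each group needs at least one sample")
    return float(two_proportion_pvalue_vec(
        np.array([k1]), n1, np.array([k0]), n0)[0])


def two_proportion_pvalue_vec(k1: np.ndarray, n1: int,
                              k0: np.ndarray, n0: int) -> np.ndarray:
    """Vectorized :func:`two_proportion_pvalue` over parallel count arrays."""
    k1 = np.asarray(k1, dtype=float)
    k0 = np.asarray(k0, dtype=float)
    pooled = (k1 + k0) / (n1 + n0)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n0)
    p = np.ones_like(pooled)
    ok = var > 0
    z = np.zeros_like(pooled)
    z[ok] = (k1[ok] / n1 - k0[ok] / n0) / np.sqrt(var[ok])
    p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    return np.minimum(p, 1.0)


def moods_median_pvalue(values: np.ndarray, labels: np.ndarray) -> float:
    """Mood's median test p-value for a numeric feature vs the class label.

    The grand median is taken over all values regardless of class; each
    sample is classified as above vs not-above it (values exactly equal
    to the median count as "not above"), and the resulting 2x2 class
    contingency table feeds a Pearson chi-squared statistic with 1 df.
    A degenerate table (any zero marginal, e.g. a constant vector)
    returns p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must have equal length")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    grand = np.median(values)
    above = values > grand
    pos = labels == classes[1]
    a = float(np.sum(above & pos))      # above, class 1
    b = float(np.sum(above & ~pos))     # above, class 0
    c = float(np.sum(~above & pos))
    d = float(np.sum(~above & ~pos))
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stats.chi2.sf(chi2, df=1))


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def mutual_information(feature: np.ndarray, kind: str,
                       labels: np.ndarray, n_bins: int = 10) -> float:
    """Plug-in mutual information (bits) between a feature and the label.

    Binary features use the exact empirical 2x2 joint table; numeric
    features are first discretized into ``n_bins`` equal-frequency bins.
    MI = H(X) + H(Y) - H(X, Y) on the empirical joint distribution; a
    single-class label vector forces MI = 0 (warned).
    """
    feature = np.asarray(feature)
    labels = np.asarray(labels)
    if len(feature) != len(labels):
        raise ValueError("feature and labels must have equal length")
    if len(np.unique(labels)) < 2:
        warnings.warn("labels contain a single class; MI is 0 by definition",
                      stacklevel=2)
        return 0.0
    if kind == "binary":
        x = np.asarray(feature, dtype=int)
    elif kind == "numeric":
        x = discretize_equal_frequency(np.asarray(feature, dtype=float), n_bins)
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    y = np.asarray(labels, dtype=int)
    joint = np.zeros((int(x.max()) + 1, 2))
    np.add.at(joint, (x, y), 1.0)
    joint /= joint.sum()
    mi = (_entropy_bits(joint.sum(axis=1)) + _entropy_bits(joint.sum(axis=0))
          - _entropy_bits(joint.ravel()))
    return max(mi, 0.0)


def binary_mutual_information_vec(k1: np.ndarray, n1: int,
                                  k0: np.ndarray, n0: int) -> np.ndarray:
    """MI in bits for many binary features from their per-class counts.

    ``k1[j]`` is the active count of feature j in the positive class of
    size ``n1`` (similarly ``k0``/``n0``).
    """
    k1 = np.asarray(k1, dtype=float)
    k0 = np.asarray(k0, dtype=float)
    n = float(n1 + n0)
    cells = np.stack([k1, n1 - k1, k0, n0 - k0], axis=0) / n  # joint p(x,y)
    px1 = (k1 + k0) / n                                       # p(x=1)
    px = np.stack([px1, 1 - px1, px1, 1 - px1], axis=0)
    py = np.array([n1 / n, n1 / n, n0 / n, n0 / n])[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = cells * np.log2(cells / (px * py))
    terms[~np.isfinite(terms)] = 0.0
    return np.maximum(terms.sum(axis=0), 0.0)


def discretize_equal_frequency(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency bin indices (0-based, duplicates merged)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, values, side="left")
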