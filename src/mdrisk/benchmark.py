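"""Imbalance-aware classification benchmark.

Protocol: the encoded dataset (usually restricted to the selected risk
factors) is split into stratified 80/20 train/test partitions, repeated
``n_partitions`` times.  Within each partition every model family is
tuned by exhaustive grid search under stratified K-fold cross-validation
with AUC as the figure of merit, refitted on the whole training split,
and scored on the test split.  Two class-balancing strategies are
compared:

* *undersampling* — the majority class of each training set is randomly
  reduced (without replacement) to the minority count;
* *weighted cost* — all training samples are kept and each sample's loss
  term is multiplied by its class weight, beta0 = Nt/(2 N0) for non-MDR
  and beta1 = Nt/(2 N1) for MDR, so both classes contribute equally to
  the aggregate cost.

Results are reported as mean +- SD of accuracy, sensitivity,
specificity and AUC over the partitions, per (family x strategy).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .encoding import Dataset
from .learners import FAMILIES, make_estimator

__all__ = [
    "ClassWeights",
    "class_weights",
    "undersample",
    "Metrics",
    "evaluate_metrics",
    "ModelSpec",
    "default_model_specs",
    "ExperimentConfig",
    "tune_hyperparameters",
    "run_benchmark",
    "PerformanceTable",
    "MDRBenchmark",
    "BenchmarkResults",
]

UNDERSAMPLING = "undersampling"
WEIGHTED_COST = "weighted_cost"


@dataclass(frozen=True)
class ClassWeights:
    """Exact class weights beta0 = Nt/(2 N0), beta1 = Nt/(2 N1).

    Stored as rationals so the balance identity
    beta0 * N0 = beta1 * N1 = Nt / 2 holds exactly.
    """

    beta0: Fraction
    beta1: Fraction
    n0: int
    n1: int

    @property
    def nt(self) -> int:
        return self.n0 + self.n1

    def sample_weights(self, y: np.ndarray) -> np.ndarray:
        """Per-sample weight vector: each sample gets its own class's beta."""
        y = np.asarray(y)
        return np.where(y == 1, float(self.beta1), float(self.beta0))


def class_weights(n0: int, n1: int) -> ClassWeights:
    """Weights that equalize the aggregate contribution of both classes."""
    if n0 < 1 or n1 < 1:
        raise ValueError("class weights are undefined for an empty class")
    nt = n0 + n1
    return ClassWeights(beta0=Fraction(nt, 2 * n0),
                        beta1=Fraction(nt, 2 * n1), n0=n0, n1=n1)


def _undersample_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    y = np.asarray(y)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    if len(idx1) == 0 or len(idx0) == 0:
        raise ValueError("both classes must be present")
    if len(idx0) >= len(idx1):
        maj, mino = idx0, idx1
    else:
        maj, mino = idx1, idx0
    keep = rng.choice(maj, size=len(mino), replace=False)
    return np.sort(np.concatenate([mino, keep]))


def undersample(dataset: Dataset, seed: int) -> Dataset:
    """Balance a dataset by subsampling the majority class.

    All minority samples are kept; the majority class is drawn without
    replacement down to the minority count.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    idx = _undersample_indices(dataset.y, rng)
    fm = dataset.features
    from .encoding import FeatureMatrix
    return Dataset(features=FeatureMatrix(X=fm.X[idx], names=fm.names,
                                          kinds=fm.kinds),
                   y=np.asarray(dataset.y)[idx])


# -- figures of merit ---------------------------------------------------------

@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "auc": self.auc}


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formulation; ties contribute 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        warnings.warn("AUC undefined with a single class present",
                      stacklevel=2)
        return float("nan")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def evaluate_metrics(labels: np.ndarray, scores: np.ndarray,
                     threshold: float = 0.5) -> Metrics:
    """Confusion-matrix metrics at ``threshold`` plus rank AUC.

    The MDR class (label 1) is the positive class for sensitivity.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if scores.min() < 0.0 or scores.max() > 1.0:
        raise ValueError("scores must lie in [0, 1]")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n1, n0 = tp + fn, tn + fp
    return Metrics(
        accuracy=(tp + tn) / len(labels) if len(labels) else float("nan"),
        sensitivity=tp / n1 if n1 else float("nan"),
        specificity=tn / n0 if n0 else float("nan"),
        auc=rank_auc(labels, scores))


# -- experiment configuration -------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A model family plus its hyperparameter grid (dict of lists)."""

    family: str
    grid: dict

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")

    def points(self) -> list[dict]:
        """Grid points in declaration order (first occurrence wins ties)."""
        keys = list(self.grid)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(self.grid[k] for k in keys))]


def default_model_specs() -> list[ModelSpec]:
    return [
        ModelSpec("LR", {"C": [0.01, 0.1, 1.0, 10.0, 100.0]}),
        ModelSpec("DT", {"max_depth": [3, 5, 10, None],
                         "min_samples_split": [2, 10, 50],
                         "min_samples_leaf": [1, 5, 20]}),
        ModelSpec("XGB", {"n_estimators": [50, 200],
                          "max_depth": [2, 3, 4],
                          "learning_rate": [0.1, 0.3]}),
        ModelSpec("SLP", {"learning_rate": [0.01, 0.1], "epochs": [200]}),
        ModelSpec("MLP", {"hidden_layer_sizes": [(8,), (16,), (16, 8)],
                          "learning_rate": [0.01, 0.1], "epochs": [200]}),
    ]


@dataclass(frozen=True)
class ExperimentConfig:
    n_partitions: int = 50
    test_fraction: float = 0.20
    cv_folds: int = 5
    balancing: tuple[str, ...] = (UNDERSAMPLING, WEIGHTED_COST)
    threshold: float = 0.5
    standardize: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_partitions < 1:
            raise ValueError("n_partitions must be >= 1")
        for b in self.balancing:
            if b not in (UNDERSAMPLING, WEIGHTED_COST):
                raise ValueError(f"unknown balancing strategy {b!r}")


# -- fitting ------------------------------------------------------------------

class _Standardizer:
    """Train-split standardization of numeric columns only.

    Binary indicators pass through; applied for LR/SLP/MLP, skipped for
    the tree families (scale-invariant splits).
    """

    def __init__(self, numeric_mask: np.ndarray):
        self.mask = numeric_mask

    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mean_ = X[:, self.mask].mean(axis=0)
        sd = X[:, self.mask].std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = X.copy()
        X[:, self.mask] = (X[:, self.mask] - self.mean_) / self.sd_
        return X


def _fit_and_score(family: str, params: dict, X_tr, y_tr, X_te, y_te,
                   balancing: str, numeric_mask, standardize: bool,
                   seed: int, threshold: float) -> Metrics:
    rng = np.random.default_rng(seed)
    sample_weight = None
    if balancing == UNDERSAMPLING:
        idx = _undersample_indices(y_tr, rng)
        X_tr, y_tr = X_tr[idx], y_tr[idx]
        n1 = int(np.sum(y_tr == 1))
        assert len(y_tr) == 2 * min(n1, len(y_tr) - n1)
    else:
        cw = class_weights(int(np.sum(y_tr == 0)), int(np.sum(y_tr == 1)))
        sample_weight = cw.sample_weights(y_tr)
        assert len(y_tr) == cw.nt
    if standardize and family in ("LR", "SLP", "MLP"):
        scaler = _Standardizer(numeric_mask).fit(X_tr)
        X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
    est = make_estimator(family, params, int(rng.integers(2 ** 31)))
    est.fit(X_tr, y_tr, sample_weight=sample_weight)
    scores = est.predict_proba(X_te)[:, 1]
    return evaluate_metrics(y_te, scores, threshold)


def tune_hyperparameters(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
                         config: ExperimentConfig, balancing: str,
                         numeric_mask: np.ndarray, seed: int) -> dict:
    """Exhaustive grid search by mean AUC over stratified K folds.

    The balancing strategy is applied inside each fold's *training*
    split only.  Ties (and duplicated grid points) resolve to the first
    point in grid order.
    """
    config.validate()
    if int(np.sum(y == 1)) < config.cv_folds or \
            int(np.sum(y == 0)) < config.cv_folds:
        raise ValueError(
            "a CV fold would lack one of the classes; reduce cv_folds or "
            "use a stratified partition / different seed")
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=seed % (2 ** 31))
    folds = list(skf.split(X, y))
    best_params, best_auc = None, -np.inf
    for p_idx, params in enumerate(spec.points()):
        aucs = []
        for f_idx, (tr, va) in enumerate(folds):
            m = _fit_and_score(
                spec.family, params, X[tr], y[tr], X[va], y[va], balancing,
                numeric_mask, config.standardize,
                seed=(seed + 1009 * p_idx + 31 * f_idx) % (2 ** 31),
                threshold=config.threshold)
            aucs.append(m.auc)
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_auc, best_params = mean_auc, params
    return best_params


@dataclass(frozen=True)
class PerformanceTable:
    """Mean +- SD of the four metrics per (family x balancing)."""

    table: pd.DataFrame          # index (family, balancing)
    raw: pd.DataFrame            # one row per partition x family x balancing

    def summary(self) -> str:
        lines = [f"{'Model':<6}{'Strategy':<16}"
                 f"{'Accuracy':<16}{'Sensitivity':<16}"
                 f"{'Specificity':<16}{'AUC':<16}"]
        for (family, balancing), row in self.table.iterrows():
            cells = []
            for metric in ("accuracy", "sensitivity", "specificity", "auc"):
                cells.append(f"{row[f'{metric}_mean']:.3f} ± "
                             f"{row[f'{metric}_sd']:.3f}")
            lines.append(f"{family:<6}{balancing:<16}" +
                         "".join(f"{c:<16}" for c in cells))
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def run_benchmark(dataset: Dataset, specs: list[ModelSpec] | None = None,
                  config: ExperimentConfig | None = None) -> PerformanceTable:
    """Repeated stratified 80/20 benchmark over families and strategies.

    Every partition shares its train/test split across families and
    strategies; within a partition each (family, balancing) pair is
    tuned by CV, refitted on the full training split and scored on the
    test split.  Fully deterministic given ``config.seed``.
    """
    specs = specs if specs is not None else default_model_specs()
    config = config or ExperimentConfig()
    config.validate()
    X = dataset.features.X
    y = np.asarray(dataset.y)
    numeric_mask = np.array([k == "numeric" for k in dataset.features.kinds])
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    part_seeds = master.integers(2 ** 31, size=config.n_partitions)
    records = []
    for p, pseed in enumerate(part_seeds):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=config.test_fraction, stratify=y,
            random_state=int(pseed))
        for spec in specs:
            for balancing in config.balancing:
                best = tune_hyperparameters(
                    X_tr, y_tr, spec, config, balancing, numeric_mask,
                    seed=int(pseed))
                m = _fit_and_score(
                    spec.family, best, X_tr, y_tr, X_te, y_te, balancing,
                    numeric_mask, config.standardize,
                    seed=int(pseed) ^ 0x5F5F, threshold=config.threshold)
                records.append({"partition": p, "family": spec.family,
                                "balancing": balancing,
                                "params": repr(best), **m.as_dict()})
    raw = pd.DataFrame.from_records(records)
    metrics = ["accuracy", "sensitivity", "specificity", "auc"]
    grouped = raw.groupby(["family", "balancing"], sort=False)[metrics]
    table = pd.concat(
        [grouped.mean().add_suffix("_mean"),
         grouped.std(ddof=1).fillna(0.0).add_suffix("_sd")], axis=1)
    order = [f"{m}_{s}" for m in metrics for s in ("mean", "sd")]
    return PerformanceTable(table=table[order], raw=raw)


# -- model/results facade -----------------------------------------------------

class MDRBenchmark:
    """Benchmark model: datasets in, Table-1-shaped performance out.

    Example::

        bench = MDRBenchmark(dataset.subset(selected), config=cfg)
        res = bench.fit()
        print(res.summary())
    """

    def __init__(self, dataset: Dataset,
                 specs: list[ModelSpec] | None = None,
                 config: ExperimentConfig | None = None):
        self.dataset = dataset
        self.specs = specs if specs is not None else default_model_specs()
        self.config = config or ExperimentConfig()

    def fit(self) -> "BenchmarkResults":
        perf = run_benchmark(self.dataset, self.specs, self.config)
        return BenchmarkResults(performance=perf, config=self.config)


@dataclass(frozen=True)
class BenchmarkResults:
    performance: PerformanceTable
    config: ExperimentConfig

    @property
    def table(self) -> pd.DataFrame:
        return self.performance.table

    @property
    def raw(self) -> pd.DataFrame:
        return self.performance.raw

    def summary(self) -> str:
        head = (f"Imbalance benchmark: {self.config.n_partitions} stratified "
                f"{int((1 - self.config.test_fraction) * 100)}/"
                f"{int(self.config.test_fraction * 100)} partitions, "
                f"{self.config.cv_folds}-fold CV tuning on AUC")
        return head + "\n\n" + self.performance.summary()
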