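"""Classifier backends for the imbalance benchmark.

Logistic regression, CART decision trees and gradient-boosted trees are
delegated to scikit-learn / xgboost, all of which accept per-sample
weights.  The single- and multi-layer perceptrons are implemented here
directly: the benchmark's weighted-cost strategy multiplies each
sample's cross-entropy term by its class weight, which requires a
backend that honours ``sample_weight`` during gradient descent.

:class:`PerceptronClassifier` is a small sklearn-compatible estimator:
sigmoid output unit, optional tanh hidden layers, full-batch Adam on the
(weighted) binary cross-entropy.  With ``hidden_layer_sizes=()`` it is
the single-layer perceptron (one neuron, a linear classifier).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

__all__ = ["PerceptronClassifier", "make_estimator", "FAMILIES"]

FAMILIES = ("LR", "DT", "XGB", "SLP", "MLP")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class PerceptronClassifier(ClassifierMixin, BaseEstimator):
    """Perceptron with sigmoid output trained on weighted cross-entropy.

    Parameters
    ----------
    hidden_layer_sizes
        Tuple of hidden-layer widths; ``()`` gives the single-layer
        perceptron (a linear decision boundary).
    learning_rate
        Adam step size.
    epochs
        Number of full-batch gradient steps.
    random_state
        Seed for weight initialization.
    """

    def __init__(self, hidden_layer_sizes=(), learning_rate: float = 0.1,
                 epochs: int = 200, random_state: int | None = None):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, d = X.shape
        if sample_weight is None:
            w = np.ones(n)
        else:
            w = np.asarray(sample_weight, dtype=float)
        w = w / w.sum()
        rng = np.random.default_rng(self.random_state)
        sizes = [d, *self.hidden_layer_sizes, 1]
        self.coefs_ = [rng.normal(0.0, np.sqrt(1.0 / sizes[i]),
                                  size=(sizes[i], sizes[i + 1]))
                       for i in range(len(sizes) - 1)]
        self.intercepts_ = [np.zeros(s) for s in sizes[1:]]
        self.classes_ = np.array([0, 1])

        # Adam state
        mW = [np.zeros_like(c) for c in self.coefs_]
        vW = [np.zeros_like(c) for c in self.coefs_]
        mb = [np.zeros_like(b) for b in self.intercepts_]
        vb = [np.zeros_like(b) for b in self.intercepts_]
        b1, b2, eps = 0.9, 0.999, 1e-8

        for t in range(1, self.epochs + 1):
            acts = [X]
            for layer, (W, b) in enumerate(zip(self.coefs_, self.intercepts_)):
                z = acts[-1] @ W + b
                acts.append(_sigmoid(z) if layer == len(self.coefs_) - 1
                            else np.tanh(z))
            yhat = acts[-1][:, 0]
            delta = ((yhat - y) * w)[:, None]  # d L / d z_out
            gW, gb = [], []
            for layer in range(len(self.coefs_) - 1, -1, -1):
                gW.append(acts[layer].T @ delta)
                gb.append(delta.sum(axis=0))
                if layer > 0:
                    delta = (delta @ self.coefs_[layer].T) * \
                        (1.0 - acts[layer] ** 2)
            gW.reverse()
            gb.reverse()
            for i in range(len(self.coefs_)):
                mW[i] = b1 * mW[i] + (1 - b1) * gW[i]
                vW[i] = b2 * vW[i] + (1 - b2) * gW[i] ** 2
                mb[i] = b1 * mb[i] + (1 - b1) * gb[i]
                vb[i] = b2 * vb[i] + (1 - b2) * gb[i] ** 2
                mw_hat = mW[i] / (1 - b1 ** t)
                vw_hat = vW[i] / (1 - b2 ** t)
                mb_hat = mb[i] / (1 - b1 ** t)
                vb_hat = vb[i] / (1 - b2 ** t)
                self.coefs_[i] -= self.learning_rate * mw_hat / \
                    (np.sqrt(vw_hat) + eps)
                self.intercepts_[i] -= self.learning_rate * mb_hat / \
                    (np.sqrt(vb_hat) + eps)
        return self

    def decision_function(self, X) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        for layer, (W, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            z = a @ W + b
            if layer == len(self.coefs_) - 1:
                return z[:, 0]
            a = np.tanh(z)
        return a[:, 0]

    def predict_proba(self, X) -> np.ndarray:
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def make_estimator(family: str, params: dict, seed: int):
    """Instantiate the backend for one model family at one grid point."""
    if family == "LR":
        return LogisticRegression(C=params["C"], solver="lbfgs",
                                  max_iter=2000, random_state=seed)
    if family == "DT":
        return DecisionTreeClassifier(criterion="gini",
                                      max_depth=params.get("max_depth"),
                                      min_samples_split=params.get(
                                          "min_samples_split", 2),
                                      min_samples_leaf=params.get(
                                          "min_samples_leaf", 1),
                                      random_state=seed)
    if family == "XGB":
        from xgboost import XGBClassifier
        return XGBClassifier(n_estimators=params["n_estimators"],
                             max_depth=params["max_depth"],
                             learning_rate=params["learning_rate"],
                             eval_metric="logloss", tree_method="hist",
                             n_jobs=1, verbosity=0, random_state=seed)
    if family == "SLP":
        return PerceptronClassifier(hidden_layer_sizes=(),
                                    learning_rate=params["learning_rate"],
                                    epochs=params["epochs"],
                                    random_state=seed)
    if family == "MLP":
        return PerceptronClassifier(
            hidden_layer_sizes=tuple(params["hidden_layer_sizes"]),
            learning_rate=params["learning_rate"],
            epochs=params["epochs"], random_state=seed)
    raise ValueError(f"unknown model family {family!r}")
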