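"""One-hot encoding of a raw cohort into a numeric design matrix.

Categorical variables are expanded with *full* one-hot encoding (one
indicator per category, no reference category dropped): the design width
for the default ICU schema is 27 + 32 + 7 + 21 + 3 + 5 = 95.  Numeric
columns and binary flags pass through unchanged.  Column order follows
schema order, with categories in declared label order; encoded columns
are named ``variable=category`` so selection results are reported by a
stable, human-readable name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import (
    BINARY,
    BINARY_GROUP,
    CATEGORICAL,
    NUMERIC,
    CohortSchema,
)
from .cohort import Cohort

__all__ = ["FeatureMatrix", "Dataset", "encode_one_hot", "feature_kinds",
           "EncodingError"]


class EncodingError(ValueError):
    """A raw value falls outside the schema's declared categories."""


@dataclass(frozen=True)
class FeatureMatrix:
    """N x d numeric design matrix with per-column names and kinds."""

    X: np.ndarray
    names: tuple[str, ...]
    kinds: tuple[str, ...]  # 'numeric' or 'binary' per column

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("X shape inconsistent with names")
        if len(self.kinds) != len(self.names):
            raise ValueError("kinds length inconsistent with names")

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=list(self.names))


@dataclass(frozen=True)
class Dataset:
    """Design matrix plus the binary MDR label vector."""

    features: FeatureMatrix
    y: np.ndarray

    def __post_init__(self) -> None:
        if len(self.y) != self.features.n:
            raise ValueError("label length does not match row count")

    @property
    def n(self) -> int:
        return self.features.n

    def subset(self, names) -> "Dataset":
        """Restrict to the given feature names (kept in matrix order)."""
        keep = [i for i, n in enumerate(self.features.names) if n in set(names)]
        fm = FeatureMatrix(
            X=self.features.X[:, keep],
            names=tuple(self.features.names[i] for i in keep),
            kinds=tuple(self.features.kinds[i] for i in keep))
        return Dataset(features=fm, y=self.y)


def encode_one_hot(cohort: Cohort, schema: CohortSchema | None = None) -> Dataset:
    """Encode a raw cohort into a :class:`Dataset`.

    Raises :class:`EncodingError` if a categorical cell holds a value not
    declared in the schema.
    """
    schema = schema or cohort.schema
    blocks: list[np.ndarray] = []
    names: list[str] = []
    kinds: list[str] = []
    table = cohort.episodes
    for v in schema:
        if v.kind == NUMERIC:
            blocks.append(table[v.name].to_numpy(dtype=float)[:, None])
            names.append(v.name)
            kinds.append("numeric")
        elif v.kind == BINARY:
            col = table[v.name].to_numpy()
            blocks.append(col.astype(float)[:, None])
            names.append(v.name)
            kinds.append("binary")
        elif v.kind == BINARY_GROUP:
            for fam in v.categories:
                blocks.append(
                    table[f"{v.name}_{fam}"].to_numpy(dtype=float)[:, None])
                names.append(f"{v.name}={fam}")
                kinds.append("binary")
        elif v.kind == CATEGORICAL:
            values = table[v.name].to_numpy(dtype=object)
            index = {c: j for j, c in enumerate(v.categories)}
            onehot = np.zeros((len(values), len(v.categories)))
            for i, val in enumerate(values):
                j = index.get(val)
                if j is None:
                    raise EncodingError(
                        f"column {v.name!r}, row {i}: value {val!r} is not a "
                        f"declared category")
                onehot[i, j] = 1.0
            blocks.append(onehot)
            names.extend(f"{v.name}={c}" for c in v.categories)
            kinds.extend("binary" for _ in v.categories)
    if blocks:
        X = np.hstack(blocks)
    else:
        X = np.empty((len(table), 0))
    fm = FeatureMatrix(X=X, names=tuple(names), kinds=tuple(kinds))
    return Dataset(features=fm, y=cohort.labels.to_numpy(dtype=np.int64))


def feature_kinds(dataset: Dataset) -> dict[str, str]:
    """Map feature name -> 'numeric' | 'binary'.

    Drives the statistical dispatch downstream: proportion tests for
    binary indicators, median tests for numeric scores.
    """
    return dict(zip(dataset.features.names, dataset.features.kinds))
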