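"""Per-cell uncertainty features derived from a probability row.

For a row ``p`` of per-label scores the four features are:

* ``P1``   — the largest entry (assurance),
* ``delta`` — gap between the two largest entries, ``P1 - P2``,
* ``admixture`` — ratio of second-best to best, ``P2 / P1``,
* ``entropy`` — Shannon entropy of the row *renormalized to sum 1*,
  divided by ``log K`` so it lies in [0, 1].

``P1``/``P2``/``delta``/``admixture`` are computed on the raw scores (they
drive thresholding against raw annotator outputs); entropy is always a
proper distribution entropy regardless of the row-normalization policy.
The log base cancels against the ``log K`` normalizer; natural log is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FEATURE_NAMES, ProbabilityMatrix, ValidationError

#: entries below this are treated as exact zeros inside x*log(x)
_ZERO_GUARD = 1e-300


@dataclass(frozen=True)
class FeatureVector:
    P1: float
    P2: float
    delta: float
    admixture: float
    entropy: float
    top_label: str
    second_label: str


@dataclass
class FeatureTable:
    """Per-cell feature vectors aligned with the source matrix.

    ``table`` is indexed by cell id with columns P1, P2, delta, admixture,
    entropy, top_label, second_label.
    """

    cell_ids: list[str]
    table: pd.DataFrame

    def matrix(self, feature_names=FEATURE_NAMES) -> np.ndarray:
        """Return the (n_cells, d) feature matrix for an ordered subset."""
        bad = [f for f in feature_names if f not in FEATURE_NAMES]
        if bad:
            raise ValidationError(f"unknown feature name(s): {bad}")
        return self.table.loc[:, list(feature_names)].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.cell_ids)

    @classmethod
    def from_arrays(cls, cell_ids, **columns) -> "FeatureTable":
        """Build a table directly from feature arrays (used by simulations)."""
        df = pd.DataFrame(columns, index=list(cell_ids))
        return cls(cell_ids=list(cell_ids), table=df)


def normalized_entropy(row: np.ndarray) -> float:
    """Entropy of ``row`` renormalized to a distribution, scaled by 1/log K."""
    row = np.asarray(row, dtype=float)
    k = row.size
    if k < 2:
        raise ValidationError("entropy needs at least 2 labels (log K normalizer)")
    total = row.sum()
    if total <= 0:
        raise ValidationError("entropy undefined for an all-zero row")
    p = row / total
    p = np.where(p < _ZERO_GUARD, 0.0, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum() / np.log(k)
    return float(min(max(h, 0.0), 1.0))


def compute_features(row: np.ndarray, labels=None) -> FeatureVector:
    """Compute the feature vector for one probability row.

    Ties at the maximum count separately: with two labels at the same top
    value, ``P2`` equals that value, so ``delta = 0`` and ``admixture = 1``.
    Label ties break toward the lower column index.
    """
    row = np.asarray(row, dtype=float)
    if row.size < 2:
        raise ValidationError("need at least 2 labels per row")
    if not (row > 0).any():
        raise ValidationError("all-zero probability row carries no identity signal")
    if labels is None:
        labels = [str(j) for j in range(row.size)]

    order = np.argsort(-row, kind="stable")  # descending value, ascending index on ties
    i1, i2 = int(order[0]), int(order[1])
    p1, p2 = float(row[i1]), float(row[i2])
    return FeatureVector(
        P1=p1,
        P2=p2,
        delta=p1 - p2,
        admixture=p2 / p1,
        entropy=normalized_entropy(row),
        top_label=str(labels[i1]),
        second_label=str(labels[i2]),
    )


def compute_feature_table(matrix: ProbabilityMatrix) -> FeatureTable:
    """Vectorized :func:`compute_features` over every cell, order preserved."""
    v = matrix.values
    n, k = v.shape

    # top-2 by stable descending sort => deterministic tie-break on column index
    order = np.argsort(-v, axis=1, kind="stable")
    i1 = order[:, 0]
    i2 = order[:, 1]
    rows = np.arange(n)
    p1 = v[rows, i1]
    p2 = v[rows, i2]
    if not (p1 > 0).all():
        bad = matrix.cell_ids[int(np.argmax(~(p1 > 0)))]
        raise ValidationError(f"cell {bad!r}: all-zero probability row")

    totals = v.sum(axis=1)
    p = v / totals[:, None]
    p = np.where(p < _ZERO_GUARD, 0.0, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    entropy = np.clip(-terms.sum(axis=1) / np.log(k), 0.0, 1.0)

    labels = np.asarray(matrix.label_ids, dtype=object)
    df = pd.DataFrame(
        {
            "P1": p1,
            "P2": p2,
            "delta": p1 - p2,
            "admixture": p2 / p1,
            "entropy": entropy,
            "top_label": labels[i1],
            "second_label": labels[i2],
        },
        index=matrix.cell_ids,
    )
    return FeatureTable(cell_ids=list(matrix.cell_ids), table=df)
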