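"""Threshold-based identity-stability groups.

Each cell is assigned exactly one of six groups from the number of labels
whose probability reaches the hard threshold ``T_h`` (and optionally a soft
threshold ``T_s < T_h``) and from whether the hit labels share a lineage
(tissue + cell class) in the hierarchy:

* ``G0``  — exactly one hard hit (single confident identity)
* ``G1``  — no hard hit (low confidence / diffuse)
* ``G2``  — >= 2 hard hits, all same lineage
* ``G3``  — >= 2 hard hits across lineages
* ``G2s`` / ``G3s`` — soft-threshold analogues: >= 2 soft hits but at most
  one hard hit.

"Exceeds the threshold" is implemented inclusively (``>=``) so exact ties
at the threshold count as hits; set ``inclusive=False`` for strict
comparison. With ``soft_overrides_g0=True`` (default) a cell with one hard
hit plus extra soft hits becomes ``G2s``/``G3s``; with ``False`` it stays
``G0`` and the soft groups only capture cells with no hard hit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io import LabelHierarchy, ProbabilityMatrix, ValidationError

GROUPS = ("G0", "G1", "G2", "G2s", "G3", "G3s")


@dataclass
class ThresholdSpec:
    hard: float
    soft: float | None = None
    adaptive: bool = False
    soft_overrides_g0: bool = True
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.hard < 1.0):
            raise ValidationError(f"hard threshold must lie in (0,1), got {self.hard}")
        if self.soft is not None and not (0.0 < self.soft < self.hard):
            raise ValidationError(
                f"soft threshold ({self.soft}) must lie in (0, hard={self.hard})"
            )


@dataclass
class GroupAssignment:
    group: str
    hard_hits: list[str] = field(default_factory=list)
    soft_hits: list[str] = field(default_factory=list)
    lineage_consistent: bool | None = None


def count_hits(
    row: np.ndarray, labels, threshold: float, inclusive: bool = True
) -> list[str]:
    """Labels whose probability reaches ``threshold``.

    Ordered by descending probability, then ascending column index.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must lie in (0,1), got {threshold}")
    row = np.asarray(row, dtype=float)
    order = np.argsort(-row, kind="stable")
    if inclusive:
        return [str(labels[j]) for j in order if row[j] >= threshold]
    return [str(labels[j]) for j in order if row[j] > threshold]


def same_lineage(
    labels, hierarchy: LabelHierarchy, missing_policy: str = "error"
) -> bool:
    """True iff every label maps to the same (tissue, cell_class) pair."""
    labels = list(labels)
    if len(labels) < 2:
        raise ValidationError("same_lineage needs at least 2 labels")
    lineages = {hierarchy.lineage(l, missing_policy) for l in labels}
    return len(lineages) == 1


def classify_cell(
    row: np.ndarray,
    labels,
    thresholds: ThresholdSpec,
    hierarchy: LabelHierarchy,
    missing_policy: str = "error",
) -> GroupAssignment:
    """Assign one cell to its group (decision table in the module docstring)."""
    hard_hits = count_hits(row, labels, thresholds.hard, thresholds.inclusive)
    soft_hits = (
        count_hits(row, labels, thresholds.soft, thresholds.inclusive)
        if thresholds.soft is not None
        else []
    )
    h = len(hard_hits)
    s = len(soft_hits)

    if h >= 2:
        consistent = same_lineage(hard_hits, hierarchy, missing_policy)
        return GroupAssignment("G2" if consistent else "G3", hard_hits, soft_hits, consistent)
    if thresholds.soft is not None and s >= 2 and (h == 0 or thresholds.soft_overrides_g0):
        consistent = same_lineage(soft_hits, hierarchy, missing_policy)
        return GroupAssignment(
            "G2s" if consistent else "G3s", hard_hits, soft_hits, consistent
        )
    if h == 1:
        return GroupAssignment("G0", hard_hits, soft_hits, None)
    return GroupAssignment("G1", hard_hits, soft_hits, None)


def classify_all(
    matrix: ProbabilityMatrix,
    thresholds: ThresholdSpec,
    hierarchy: LabelHierarchy,
    missing_policy: str = "error",
) -> tuple[list[GroupAssignment], dict[str, float]]:
    """Classify every cell; also return the per-group fraction summary.

    Rows where no multi-hit logic can trigger take a fast path; only rows
    with >= 2 soft hits need the full per-row treatment.
    """
    v = matrix.values
    labels = matrix.label_ids
    cmp = np.greater_equal if thresholds.inclusive else np.greater
    hard_counts = cmp(v, thresholds.hard).sum(axis=1)
    if thresholds.soft is not None:
        soft_counts = cmp(v, thresholds.soft).sum(axis=1)
    else:
        soft_counts = np.zeros(len(v), dtype=int)

    assignments: list[GroupAssignment] = []
    for i in range(len(v)):
        if hard_counts[i] <= 1 and soft_counts[i] <= 1:
            soft = (
                count_hits(v[i], labels, thresholds.soft, thresholds.inclusive)
                if thresholds.soft is not None and soft_counts[i]
                else []
            )
            if hard_counts[i] == 1:
                hit = count_hits(v[i], labels, thresholds.hard, thresholds.inclusive)
                assignments.append(GroupAssignment("G0", hit, soft))
            else:
                assignments.append(GroupAssignment("G1", [], soft))
            continue
        try:
            assignments.append(
                classify_cell(v[i], labels, thresholds, hierarchy, missing_policy)
            )
        except ValidationError as exc:
            raise ValidationError(f"cell {matrix.cell_ids[i]!r}: {exc}") from exc

    counts = Counter(a.group for a in assignments)
    n = len(assignments)
    summary = {g: counts.get(g, 0) / n for g in GROUPS}
    return assignments, summary


def suggest_thresholds(p1_values: np.ndarray) -> ThresholdSpec:
    """Adaptive threshold suggestion from the spread of top probabilities.

    ``T_h`` is the Tukey lower fence of the P1 distribution,
    ``Q1 - 1.5 * IQR`` (linear-interpolation quantiles), clipped into
    [0.05, 0.95]; ``T_s = T_h / 2`` clipped into [0.01, T_h - 1e-6].
    """
    p1 = np.asarray(p1_values, dtype=float)
    if p1.size < 4:
        raise ValidationError("adaptive thresholds need at least 4 P1 values")
    q1, q3 = np.quantile(p1, [0.25, 0.75])  # linear interpolation (type 7)
    iqr = q3 - q1
    t_h = float(np.clip(q1 - 1.5 * iqr, 0.05, 0.95))
    t_s = float(np.clip(t_h / 2.0, 0.01, t_h - 1e-6))
    return ThresholdSpec(hard=t_h, soft=t_s, adaptive=True)
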