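"""Synthetic probability matrices with known ground truth.

Rows are compositional, so regimes are Dirichlet mixtures:

* ``stable``  — one dominant concentration (high-assurance single identity),
* ``diffuse`` — symmetric moderate concentration (no label clears a
  sensible hard threshold),
* ``within_lineage_bimodal`` / ``cross_lineage_bimodal`` — two dominant
  concentrations on a label pair drawn within one lineage or across two.

With the packaged default concentrations and a hard threshold of
``DEFAULT_HARD`` the four regimes map onto groups G0/G1/G2/G3 with >= 95%
accuracy. Condition datasets perturb a fraction of query cells by mixing
their rows toward the uniform distribution, with the mixing weight
calibrated so named features shift by a requested number of reference
standard deviations. All randomness flows through one seeded generator per
call; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .features import compute_feature_table
from .io import (
    FEATURE_NAMES,
    CellMetadata,
    LabelHierarchy,
    ProbabilityMatrix,
    ValidationError,
)

# packaged default concentrations (see module docstring)
STABLE_DOMINANT = 50.0
BIMODAL_DOMINANT = 100.0
BACKGROUND = 0.1
DIFFUSE = 8.0
#: hard threshold at which the packaged regimes separate into G0/G1/G2/G3
DEFAULT_HARD = 0.4

REGIMES = ("stable", "diffuse", "within_lineage_bimodal", "cross_lineage_bimodal")

CONDITION_COLUMN = "condition"
CLUSTER_COLUMN = "cluster"
REFERENCE_LEVEL = "control"
QUERY_LEVEL = "case"


@dataclass
class RegimeSpec:
    regime: str
    n_cells: int
    K: int = 5
    dominant: float = STABLE_DOMINANT
    bimodal_dominant: float = BIMODAL_DOMINANT
    background: float = BACKGROUND
    diffuse: float = DIFFUSE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValidationError(f"unknown regime {self.regime!r}")
        if self.n_cells < 1 or self.K < 2:
            raise ValidationError("need n_cells >= 1 and K >= 2")
        if min(self.dominant, self.bimodal_dominant, self.background, self.diffuse) <= 0:
            raise ValidationError("all concentrations must be positive")


@dataclass
class ShiftSpec:
    """A condition shift in feature space, in reference-SD units."""

    features: tuple[str, ...] = ("entropy",)
    magnitude: float = 0.0
    affected_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.affected_fraction <= 1.0):
            raise ValidationError("affected_fraction must lie in [0,1]")
        if self.magnitude < 0:
            raise ValidationError("shift magnitude must be >= 0")


def default_hierarchy(K: int) -> LabelHierarchy:
    """Two-lineage hierarchy over labels L0..L{K-1}.

    The first ceil(K/2)+ labels form lineage A, the rest lineage B; both
    lineages hold >= 2 labels for K >= 4.
    """
    if K < 2:
        raise ValidationError("need K >= 2")
    split = max(2, (K + 1) // 2) if K >= 4 else 1
    entries = {}
    for j in range(K):
        side = "A" if j < split else "B"
        entries[f"L{j}"] = {"tissue": f"tissue{side}", "cell_class": f"class{side}"}
    return LabelHierarchy.from_mapping(entries)


def _lineage_groups(hierarchy: LabelHierarchy, labels: list[str]) -> list[list[int]]:
    groups: dict[tuple[str, str], list[int]] = {}
    for j, label in enumerate(labels):
        groups.setdefault(hierarchy.lineage(label), []).append(j)
    return list(groups.values())


def _dirichlet_rows(rng: np.random.Generator, conc: np.ndarray) -> np.ndarray:
    """Row-wise Dirichlet draws via the gamma trick (vectorized)."""
    g = rng.gamma(shape=conc)
    return g / g.sum(axis=1, keepdims=True)


def simulate_matrix(
    spec: RegimeSpec, hierarchy: LabelHierarchy | None = None
) -> tuple[ProbabilityMatrix, list[str]]:
    """Draw a probability matrix for one regime; returns (matrix, truth).

    ``truth`` holds the group each cell is engineered to receive under the
    packaged default thresholds (G0/G1/G2/G3 for the four regimes).
    """
    if hierarchy is None:
        hierarchy = default_hierarchy(spec.K)
    labels = [f"L{j}" for j in range(spec.K)]
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_cells, spec.K
    conc = np.full((n, k), spec.background)

    if spec.regime == "stable":
        dom = rng.integers(0, k, size=n)
        conc[np.arange(n), dom] = spec.dominant
        truth = "G0"
    elif spec.regime == "diffuse":
        conc[:] = spec.diffuse
        truth = "G1"
    else:
        groups = _lineage_groups(hierarchy, labels)
        if spec.regime == "within_lineage_bimodal":
            eligible = [g for g in groups if len(g) >= 2]
            if not eligible:
                raise ValidationError("no lineage holds 2+ labels")
            for i in range(n):
                g = eligible[rng.integers(0, len(eligible))]
                pair = rng.choice(g, size=2, replace=False)
                conc[i, pair] = spec.bimodal_dominant
            truth = "G2"
        else:  # cross_lineage_bimodal
            if len(groups) < 2:
                raise ValidationError(
                    "cross-lineage regime needs a hierarchy with >= 2 lineages"
                )
            for i in range(n):
                ga, gb = rng.choice(len(groups), size=2, replace=False)
                conc[i, groups[ga][rng.integers(0, len(groups[ga]))]] = spec.bimodal_dominant
                conc[i, groups[gb][rng.integers(0, len(groups[gb]))]] = spec.bimodal_dominant
            truth = "G3"

    values = _dirichlet_rows(rng, conc)
    cell_ids = [f"cell{idx}" for idx in range(n)]
    return ProbabilityMatrix(cell_ids, labels, values), [truth] * n


def _feature_means_sds(values: np.ndarray, labels: list[str], names) -> tuple[np.ndarray, np.ndarray]:
    ids = [f"t{i}" for i in range(len(values))]
    ft = compute_feature_table(ProbabilityMatrix(ids, labels, values))
    x = ft.matrix(tuple(names))
    return x.mean(axis=0), x.std(axis=0, ddof=1)


def _calibrate_mixing(
    ref_values: np.ndarray,
    target_values: np.ndarray,
    labels: list[str],
    names,
    magnitude: float,
) -> float:
    """Bisect the uniform-mixing weight w so the named features move by
    ``magnitude`` reference SDs (averaged across targets)."""
    ref_mean, ref_sd = _feature_means_sds(ref_values, labels, names)
    ref_sd = np.where(ref_sd > 0, ref_sd, np.inf)
    k = ref_values.shape[1]
    uniform = np.full(k, 1.0 / k)

    def standardized_shift(w: float) -> float:
        mixed = (1.0 - w) * target_values + w * uniform
        mean_w, _ = _feature_means_sds(mixed, labels, names)
        return float(np.mean(np.abs(mean_w - ref_mean) / ref_sd))

    if magnitude == 0.0:
        return 0.0
    lo, hi = 0.0, 1.0
    if standardized_shift(1.0) < magnitude:
        return 1.0  # requested shift unattainable by uniform mixing; saturate
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if standardized_shift(mid) < magnitude:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_condition_dataset(
    n_ref: int,
    n_query: int,
    clusters: int,
    shift: ShiftSpec,
    seed: int,
    K: int = 5,
    feature_subset=FEATURE_NAMES,
) -> tuple[ProbabilityMatrix, CellMetadata]:
    """Reference (control) + query (case) cells with a calibrated shift.

    Reference cells come from the stable regime; a fraction of query cells
    is mixed toward the uniform row so the shifted features move by
    ``shift.magnitude`` reference SDs. Metadata gains ``condition`` and
    ``cluster`` columns (clusters in equal proportions).
    """
    import pandas as pd

    bad = [f for f in shift.features if f not in feature_subset]
    if bad:
        raise ValidationError(
            f"shift targets feature(s) outside the configured subset: {bad}"
        )
    if n_ref < 1 or n_query < 1 or clusters < 1:
        raise ValidationError("need n_ref, n_query, clusters >= 1")

    rng = np.random.default_rng(seed)
    ref_spec = RegimeSpec("stable", n_ref, K=K, seed=int(rng.integers(2**31)))
    qry_spec = RegimeSpec("stable", n_query, K=K, seed=int(rng.integers(2**31)))
    ref_m, _ = simulate_matrix(ref_spec)
    qry_m, _ = simulate_matrix(qry_spec)
    labels = ref_m.label_ids

    values_q = qry_m.values.copy()
    n_affected = int(round(shift.affected_fraction * n_query))
    if shift.magnitude > 0 and n_affected > 0:
        affected = rng.choice(n_query, size=n_affected, replace=False)
        w = _calibrate_mixing(
            ref_m.values, values_q[affected], labels, shift.features, shift.magnitude
        )
        uniform = np.full(K, 1.0 / K)
        values_q[affected] = (1.0 - w) * values_q[affected] + w * uniform

    values = np.vstack([ref_m.values, values_q])
    cell_ids = [f"ref{idx}" for idx in range(n_ref)] + [f"qry{idx}" for idx in range(n_query)]
    matrix = ProbabilityMatrix(cell_ids, labels, values)

    condition = np.array([REFERENCE_LEVEL] * n_ref + [QUERY_LEVEL] * n_query, dtype=object)
    cluster_ids = np.array(
        [f"c{idx % clusters}" for idx in range(n_ref)]
        + [f"c{idx % clusters}" for idx in range(n_query)],
        dtype=object,
    )
    table = pd.DataFrame(
        {CONDITION_COLUMN: condition, CLUSTER_COLUMN: cluster_ids}, index=cell_ids
    )
    return matrix, CellMetadata(cell_ids=cell_ids, table=table)


def split_top_probability(
    row: np.ndarray, alpha: float, donor_index: int | None = None
) -> np.ndarray:
    """Move a (1 - alpha) share of the top probability onto a donor label.

    The top entry ``p`` becomes ``alpha * p`` and the donor gains
    ``(1 - alpha) * p``; all other entries (and the row total) are
    unchanged. The default donor is the second-best label.
    """
    row = np.asarray(row, dtype=float)
    if not (0.0 < alpha <= 1.0):
        raise ValidationError("alpha must lie in (0, 1]")
    order = np.argsort(-row, kind="stable")
    top = int(order[0])
    donor = int(order[1]) if donor_index is None else int(donor_index)
    if donor == top:
        raise ValidationError("donor label must differ from the top label")
    out = row.copy()
    moved = (1.0 - alpha) * out[top]
    out[top] -= moved
    out[donor] += moved
    return out


def write_fixture(
    out_dir: str | Path,
    n_ref: int = 300,
    n_query: int = 300,
    clusters: int = 2,
    shift: ShiftSpec | None = None,
    seed: int = 0,
    K: int = 5,
) -> dict[str, str]:
    """Write a self-contained fixture directory (CSV/JSON/YAML).

    The directory is directly consumable by the end-to-end pipeline via
    the emitted ``config.yaml``.
    """
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shift = shift or ShiftSpec(magnitude=2.0)
    matrix, metadata = simulate_condition_dataset(
        n_ref, n_query, clusters, shift, seed=seed, K=K
    )
    hierarchy = default_hierarchy(K)

    paths = {
        "prob_matrix": str(out / "probabilities.csv"),
        "metadata": str(out / "metadata.csv"),
        "hierarchy": str(out / "hierarchy.json"),
        "config": str(out / "config.yaml"),
    }
    matrix.to_frame().to_csv(paths["prob_matrix"], index_label="cell_id", float_format="%.17g")
    metadata.table.to_csv(paths["metadata"], index_label="cell_id")
    with open(paths["hierarchy"], "w", encoding="utf-8") as fh:
        json.dump(hierarchy.to_mapping(), fh, indent=2)
        fh.write("\n")

    config = {
        "prob_matrix": paths["prob_matrix"],
        "metadata": paths["metadata"],
        "hierarchy": paths["hierarchy"],
        "output_dir": str(out / "results"),
        "renormalize_rows": False,
        "features": list(FEATURE_NAMES),
        "thresholds": {"hard": DEFAULT_HARD, "soft": DEFAULT_HARD / 2, "adaptive": False},
        "reference": {
            "condition_column": CONDITION_COLUMN,
            "reference_level": REFERENCE_LEVEL,
            "cluster_column": CLUSTER_COLUMN,
            "min_cells": 50,
            "shrinkage_lambda": 0.1,
            "ridge_epsilon": 1e-8,
        },
        "enrichment": {
            "quantile": 0.9,
            "test": "binomial",
            "n_permutations": 1000,
            "seed": seed,
        },
    }
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return paths
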