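"""Readers, writers and validated domain types for all on-disk artifacts.

On-disk formats are deliberately plain: probability matrices and cell
metadata are UTF-8 comma-separated CSV with a header row and the cell id
in the first column, the label hierarchy is a JSON object, run
configuration is YAML, and results are CSV plus a JSON manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("oorkit")

#: tolerance for clipping slightly-out-of-range probabilities from upstream numerics
CLIP_TOL = 1e-6
#: row sums deviating from 1 by more than this trigger a prominent warning
ROW_SUM_WARN_TOL = 1e-3

FEATURE_NAMES = ("P1", "delta", "admixture", "entropy")


class ValidationError(ValueError):
    """Raised when an input file violates a structural or numeric contract."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed at all."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ProbabilityMatrix:
    """Dense cells x labels table of per-class annotation probabilities.

    Attributes
    ----------
    cell_ids : list of str
        Unique row identifiers, in file order.
    label_ids : list of str
        Unique candidate-label identifiers (K >= 2), in file order.
    values : ndarray of shape (n_cells, K)
        Probabilities in [0, 1]; every row has at least one positive entry.
        Rows are *not* required to sum to 1 (one-vs-rest annotator scores
        commonly do not); see :func:`read_probability_matrix`.
    row_sum_report : dict or None
        ``{"min_deviation": float, "max_deviation": float}`` recording how
        far the raw row sums were from 1, for logging/manifest purposes.
    """

    cell_ids: list[str]
    label_ids: list[str]
    values: np.ndarray
    row_sum_report: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if len(self.cell_ids) != n:
            raise ValidationError("cell_ids length does not match value rows")
        if len(self.label_ids) != k:
            raise ValidationError("label_ids length does not match value columns")
        if k < 2:
            raise ValidationError("probability matrix needs at least 2 labels")
        _check_unique(self.cell_ids, "cell id")
        _check_unique(self.label_ids, "label id")
        self.values = _validate_probabilities(self.values, self.cell_ids, self.label_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_labels(self) -> int:
        return len(self.label_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.label_ids)


@dataclass
class CellMetadata:
    """Per-cell categorical metadata aligned 1:1 with a probability matrix."""

    cell_ids: list[str]
    table: pd.DataFrame  # indexed by cell id, same order as cell_ids

    def __post_init__(self) -> None:
        if list(self.table.index) != list(self.cell_ids):
            raise ValidationError("metadata table index must equal cell_ids in order")

    def column(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise ValidationError(f"metadata is missing required column {name!r}")
        return self.table[name].to_numpy()

    def has_column(self, name: str) -> bool:
        return name in self.table.columns


@dataclass
class LabelHierarchy:
    """Mapping from annotation label to its (tissue, cell_class) lineage."""

    entries: dict[str, tuple[str, str]]

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Mapping[str, str]]) -> "LabelHierarchy":
        entries: dict[str, tuple[str, str]] = {}
        for label, rec in raw.items():
            if not isinstance(rec, Mapping):
                raise ValidationError(f"hierarchy entry for {label!r} must be an object")
            missing = [k for k in ("tissue", "cell_class") if k not in rec]
            if missing:
                raise ValidationError(
                    f"hierarchy entry for {label!r} is missing {', '.join(missing)}"
                )
            entries[str(label)] = (str(rec["tissue"]), str(rec["cell_class"]))
        return cls(entries)

    def lineage(self, label: str, missing_policy: str = "error") -> tuple[str, str]:
        """Resolve ``label`` to its lineage.

        ``missing_policy`` is either ``"error"`` or ``"own-lineage"`` (each
        unknown label becomes its own singleton lineage).
        """
        if label in self.entries:
            return self.entries[label]
        if missing_policy == "own-lineage":
            return (label, label)
        raise ValidationError(f"label {label!r} is not present in the hierarchy")

    def to_mapping(self) -> dict[str, dict[str, str]]:
        return {
            label: {"tissue": t, "cell_class": c} for label, (t, c) in self.entries.items()
        }


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class ThresholdConfig:
    hard: float = 0.5
    soft: float | None = None
    adaptive: bool = False
    soft_overrides_g0: bool = True
    inclusive: bool = True

    def validate(self) -> None:
        if not (0.0 < self.hard < 1.0):
            raise ValidationError(f"hard threshold must lie in (0,1), got {self.hard}")
        if self.soft is not None:
            if not (0.0 < self.soft < self.hard):
                raise ValidationError(
                    f"soft threshold ({self.soft}) must lie in (0, hard={self.hard})"
                )


@dataclass
class ReferenceConfig:
    condition_column: str = "condition"
    reference_level: str = "control"
    cluster_column: str | None = None
    min_cells: int = 50
    shrinkage_lambda: float = 0.1
    ridge_epsilon: float = 1e-8

    def validate(self) -> None:
        if not (0.0 <= self.shrinkage_lambda <= 1.0):
            raise ValidationError("shrinkage_lambda must lie in [0,1]")
        if self.ridge_epsilon < 0:
            raise ValidationError("ridge_epsilon must be >= 0")
        if self.min_cells < 1:
            raise ValidationError("min_cells must be >= 1")


@dataclass
class EnrichmentConfig:
    quantile: float = 0.9
    test: str = "binomial"  # "binomial" | "permutation"
    n_permutations: int = 1000
    seed: int = 0
    in_sample_p0: bool = False

    def validate(self) -> None:
        if not (0.0 < self.quantile < 1.0):
            raise ValidationError("enrichment quantile must lie in (0,1)")
        if self.test not in ("binomial", "permutation"):
            raise ValidationError(f"unknown enrichment test {self.test!r}")
        if self.test == "permutation" and self.n_permutations < 100:
            raise ValidationError("n_permutations must be >= 100")


@dataclass
class RunConfig:
    """Validated run configuration (mirrors the YAML schema)."""

    prob_matrix: str = ""
    metadata: str = ""
    hierarchy: str = ""
    output_dir: str = "."
    renormalize_rows: bool = False
    missing_label_policy: str = "error"  # "error" | "own-lineage"
    features: tuple[str, ...] = FEATURE_NAMES
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    def validate(self) -> None:
        self.thresholds.validate()
        self.reference.validate()
        self.enrichment.validate()
        if self.missing_label_policy not in ("error", "own-lineage"):
            raise ValidationError(
                f"unknown missing_label_policy {self.missing_label_policy!r}"
            )
        if len(self.features) == 0:
            raise ValidationError("feature subset must not be empty")
        bad = [f for f in self.features if f not in FEATURE_NAMES]
        if bad:
            raise ValidationError(f"unknown feature name(s): {bad}")
        if len(set(self.features)) != len(self.features):
            raise ValidationError("duplicate feature names in subset")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw or {})
        cfg = cls(
            prob_matrix=str(raw.get("prob_matrix", "")),
            metadata=str(raw.get("metadata", "")),
            hierarchy=str(raw.get("hierarchy", "")),
            output_dir=str(raw.get("output_dir", ".")),
            renormalize_rows=bool(raw.get("renormalize_rows", False)),
            missing_label_policy=str(raw.get("missing_label_policy", "error")),
            features=tuple(raw.get("features", FEATURE_NAMES)),
            thresholds=ThresholdConfig(**dict(raw.get("thresholds", {}))),
            reference=ReferenceConfig(**dict(raw.get("reference", {}))),
            enrichment=EnrichmentConfig(**dict(raw.get("enrichment", {}))),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            try:
                raw = yaml.safe_load(fh)
            except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
                raise ParseError(f"could not parse YAML config {path}: {exc}") from exc
        return cls.from_dict(raw or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["features"] = list(self.features)
        return d


# ---------------------------------------------------------------------------
# Validation helpers
# ---------------------------------------------------------------------------


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


def _validate_probabilities(
    values: np.ndarray, cell_ids: Sequence[str], label_ids: Sequence[str]
) -> np.ndarray:
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"non-finite probability for cell {cell_ids[i]!r}, label {label_ids[j]!r}"
        )
    too_low = values < -CLIP_TOL
    too_high = values > 1.0 + CLIP_TOL
    if too_low.any() or too_high.any():
        i, j = np.argwhere(too_low | too_high)[0]
        raise ValidationError(
            f"probability out of [0,1] for cell {cell_ids[i]!r}, label "
            f"{label_ids[j]!r}: {values[i, j]!r}"
        )
    values = np.clip(values, 0.0, 1.0)
    empty = ~(values > 0).any(axis=1)
    if empty.any():
        i = int(np.argmax(empty))
        raise ValidationError(f"cell {cell_ids[i]!r} has an all-zero probability row")
    return values


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_probability_matrix(path: str | Path, renormalize: bool = False) -> ProbabilityMatrix:
    """Read a cells x labels probability CSV.

    The first column holds the cell id; the header row holds the label ids.
    With ``renormalize=True`` each row with a positive sum is divided by its
    sum so that rows become proper distributions; this is idempotent on rows
    that already sum to 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise ParseError(f"could not parse probability CSV {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValidationError("probability matrix needs at least 2 label columns")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric probability for cell {df.index[i]!r}, "
            f"label {df.columns[j]!r}: {df.iat[i, j]!r}"
        )

    cell_ids = [str(c) for c in df.index]
    label_ids = [str(c) for c in df.columns]
    values = _validate_probabilities(numeric.to_numpy(dtype=float), cell_ids, label_ids)

    sums = values.sum(axis=1)
    report = {
        "min_deviation": float((sums - 1.0).min()),
        "max_deviation": float((sums - 1.0).max()),
    }
    if max(abs(report["min_deviation"]), abs(report["max_deviation"])) > ROW_SUM_WARN_TOL:
        logger.warning(
            "probability rows deviate from sum 1 (min %+.3g, max %+.3g); raw "
            "per-class scores are used as-is unless renormalize_rows is set",
            report["min_deviation"],
            report["max_deviation"],
        )
    if renormalize:
        pos = sums > 0
        values = values.copy()
        values[pos] = values[pos] / sums[pos, None]

    return ProbabilityMatrix(cell_ids, label_ids, values, row_sum_report=report)


def read_metadata(
    path: str | Path,
    matrix: "ProbabilityMatrix | Sequence[str]",
    id_column: str | None = None,
    require_columns: Sequence[str] = (),
) -> CellMetadata:
    """Read per-cell metadata and align it to the matrix cell order.

    ``matrix`` may be a :class:`ProbabilityMatrix` or a plain sequence of
    cell ids. Metadata rows not present in the matrix are dropped with a
    warning; matrix cells missing from the metadata are an error (the
    downstream contract requires exact 1:1 alignment).
    """
    cell_order = list(matrix.cell_ids) if hasattr(matrix, "cell_ids") else [str(c) for c in matrix]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise ParseError(f"could not parse metadata CSV {path}: {exc}") from exc
    if df.shape[1] < 1:
        raise ValidationError("metadata CSV has no columns")
    id_col = id_column if id_column is not None else df.columns[0]
    if id_col not in df.columns:
        raise ValidationError(f"metadata is missing the id column {id_col!r}")
    df[id_col] = df[id_col].astype(str)
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValidationError(f"duplicate cell id in metadata: {dup!r}")
    df = df.set_index(id_col)

    matrix_ids = set(cell_order)
    meta_ids = set(df.index)
    overlap = matrix_ids & meta_ids
    if not overlap:
        raise ValidationError("metadata and probability matrix share no cell ids")
    extra = sorted(meta_ids - matrix_ids)
    if extra:
        logger.warning(
            "dropping %d metadata cell(s) absent from the probability matrix: %s",
            len(extra),
            ", ".join(extra[:10]) + ("..." if len(extra) > 10 else ""),
        )
    missing = sorted(matrix_ids - meta_ids)
    if missing:
        raise ValidationError(
            f"{len(missing)} matrix cell(s) have no metadata row, e.g. {missing[:5]}"
        )
    df = df.loc[cell_order]

    for col in require_columns:
        if col not in df.columns:
            raise ValidationError(f"metadata is missing required column {col!r}")
    return CellMetadata(cell_ids=cell_order, table=df)


def read_hierarchy(path: str | Path) -> LabelHierarchy:
    """Read a label -> {tissue, cell_class} hierarchy JSON file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"could not parse hierarchy JSON {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ValidationError("hierarchy JSON must be an object mapping labels to records")
    return LabelHierarchy.from_mapping(raw)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

# full float precision so a round-trip read reproduces values bit-for-bit
_FLOAT_FORMAT = "%.17g"


def write_results(
    out_dir: str | Path,
    cells: pd.DataFrame,
    clusters: pd.DataFrame,
    manifest: Mapping,
) -> dict[str, str]:
    """Write ``cells.csv``, ``clusters.csv`` and ``manifest.json``.

    ``cells`` must be indexed by cell id. Returns the file manifest
    (logical name -> path written).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    paths = {
        "cells": str(out / "cells.csv"),
        "clusters": str(out / "clusters.csv"),
        "manifest": str(out / "manifest.json"),
    }
    cells.to_csv(paths["cells"], index=True, index_label="cell_id", float_format=_FLOAT_FORMAT)
    clusters.to_csv(paths["clusters"], index=False, float_format=_FLOAT_FORMAT)
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(dict(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_cells_csv(path: str | Path) -> pd.DataFrame:
    """Read back a ``cells.csv`` written by :func:`write_results`."""
    return pd.read_csv(path, index_col="cell_id")


def read_clusters_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
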