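"""End-to-end orchestration: read -> features -> classify -> reference ->
OOR -> summaries -> write, plus the stage functions behind the CLI
subcommands. Identical (inputs, config, seed) produce byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import GroupAssignment, ThresholdSpec, classify_all, suggest_thresholds
from .features import FeatureTable, compute_feature_table
from .io import (
    CellMetadata,
    RunConfig,
    ValidationError,
    read_hierarchy,
    read_metadata,
    read_probability_matrix,
    write_results,
)
from .reference import fit_reference, score_all
from .stats import ClusterSummary, summarize_clusters

logger = logging.getLogger("oorkit")


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def threshold_spec_from_config(config: RunConfig, p1_values=None) -> ThresholdSpec:
    t = config.thresholds
    if t.adaptive:
        if p1_values is None:
            raise ValidationError("adaptive thresholds need P1 values")
        spec = suggest_thresholds(p1_values)
        spec.soft_overrides_g0 = t.soft_overrides_g0
        spec.inclusive = t.inclusive
        return spec
    return ThresholdSpec(
        hard=t.hard,
        soft=t.soft,
        adaptive=False,
        soft_overrides_g0=t.soft_overrides_g0,
        inclusive=t.inclusive,
    )


def cells_frame(
    features: FeatureTable,
    assignments: list[GroupAssignment] | None = None,
    metadata: CellMetadata | None = None,
    config: RunConfig | None = None,
    oor_result=None,
) -> pd.DataFrame:
    """Assemble the per-cell output table from whichever stages have run."""
    df = features.table.copy()
    if assignments is not None:
        df["group"] = [a.group for a in assignments]
        df["n_hard_hits"] = [len(a.hard_hits) for a in assignments]
        df["n_soft_hits"] = [len(a.soft_hits) for a in assignments]
    if metadata is not None and config is not None:
        df[config.reference.condition_column] = metadata.column(
            config.reference.condition_column
        )
        if config.reference.cluster_column is not None:
            df[config.reference.cluster_column] = metadata.column(
                config.reference.cluster_column
            )
    if oor_result is not None:
        df["oor"] = oor_result.oor
        df["cluster_used"] = oor_result.cluster_used
        df["fallback_used"] = oor_result.fallback_used
    return df


def clusters_frame(summaries: list[ClusterSummary]) -> pd.DataFrame:
    cols = [
        "cluster", "n_ref", "n_query", "median_ref", "median_query", "median_shift",
        "tail_quantile", "tail_threshold", "tail_fraction", "expected_fraction",
        "p_value", "q_value", "test", "fallback_used",
    ]
    if not summaries:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([asdict(s) for s in summaries])[cols]


def run_pipeline(config: RunConfig, make_plots: bool = False) -> dict:
    """Run every stage and write cells.csv / clusters.csv / manifest.json.

    Returns the manifest dictionary.
    """
    config.validate()
    timings: dict[str, float] = {}
    warnings: list[str] = []

    t0 = time.perf_counter()
    matrix = read_probability_matrix(config.prob_matrix, config.renormalize_rows)
    rep = matrix.row_sum_report or {}
    if rep and max(abs(rep.get("min_deviation", 0)), abs(rep.get("max_deviation", 0))) > 1e-3:
        warnings.append(
            f"row sums deviate from 1 (min {rep['min_deviation']:+.3g}, "
            f"max {rep['max_deviation']:+.3g})"
        )
    require = [config.reference.condition_column]
    if config.reference.cluster_column is not None:
        require.append(config.reference.cluster_column)
    metadata = read_metadata(config.metadata, matrix, require_columns=require)
    hierarchy = read_hierarchy(config.hierarchy)
    timings["read"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    features = compute_feature_table(matrix)
    timings["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    thresholds = threshold_spec_from_config(config, features.table["P1"].to_numpy())
    assignments, group_fractions = classify_all(
        matrix, thresholds, hierarchy, config.missing_label_policy
    )
    timings["classify"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    model = fit_reference(features, metadata, config)
    fallback_clusters = sorted(
        c for c, st in model.per_cluster.items() if st.fallback_used
    )
    if fallback_clusters:
        warnings.append(
            "global-fallback reference used for cluster(s): "
            + ", ".join(fallback_clusters)
        )
    oor_result = score_all(
        features, model, metadata, config.reference.cluster_column
    )
    timings["score"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    summaries, skipped = summarize_clusters(oor_result, metadata, config)
    if skipped:
        warnings.append(
            "cluster(s) skipped (missing reference or query cells): "
            + ", ".join(skipped)
        )
    timings["summarize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cells = cells_frame(features, assignments, metadata, config, oor_result)
    clusters = clusters_frame(summaries)
    manifest = {
        "package": "oorkit",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.enrichment.seed,
        "thresholds_used": {
            "hard": thresholds.hard,
            "soft": thresholds.soft,
            "adaptive": thresholds.adaptive,
        },
        "group_fractions": group_fractions,
        "row_sum_report": matrix.row_sum_report,
        "input_digests": {
            "prob_matrix": _digest(config.prob_matrix),
            "metadata": _digest(config.metadata),
            "hierarchy": _digest(config.hierarchy),
        },
        "reference_model": model.to_dict(),
        "skipped_clusters": skipped,
        "warnings": warnings,
        "timings_sec": {k: round(v, 6) for k, v in timings.items()},
    }
    paths = write_results(config.output_dir, cells, clusters, manifest)
    manifest["files"] = paths
    timings["write"] = time.perf_counter() - t0

    if make_plots:
        from .plots import quicklook_plots

        quicklook_plots(cells, config, Path(config.output_dir))
    logger.info("pipeline complete: %d cells, %d cluster summaries", len(cells), len(clusters))
    return manifest
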