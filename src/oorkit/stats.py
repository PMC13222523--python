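"""Cluster-level OOR summaries and tail-enrichment tests.

The reference (control) OOR distribution serves as an empirical null.
Per cluster we report the median shift between conditions and the fraction
of query cells whose score strictly exceeds a reference quantile, tested
either against the nominal exceedance rate with a one-sided binomial test
or by permutation within the cluster. P-values are adjusted across
clusters with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .io import CellMetadata, RunConfig, ValidationError
from .reference import OORResult

logger = logging.getLogger("oorkit")

# smallest positive subnormal double; p-values are clamped here so that an
# underflowing binomial survival probability stays inside (0, 1]
_TINY_P = 5e-324


@dataclass
class ClusterSummary:
    cluster: str
    n_ref: int
    n_query: int
    median_ref: float
    median_query: float
    median_shift: float
    tail_quantile: float
    tail_threshold: float
    tail_fraction: float
    expected_fraction: float
    p_value: float
    q_value: float
    test: str
    fallback_used: bool = False


def median_shift(ref_scores: np.ndarray, query_scores: np.ndarray) -> float:
    """median(query) - median(ref); even-length medians use the midpoint."""
    ref_scores = np.asarray(ref_scores, dtype=float)
    query_scores = np.asarray(query_scores, dtype=float)
    if ref_scores.size == 0 or query_scores.size == 0:
        raise ValidationError("median_shift needs nonempty score vectors")
    return float(np.median(query_scores) - np.median(ref_scores))


def tail_enrichment(
    ref_scores: np.ndarray, query_scores: np.ndarray, q: float
) -> dict:
    """Fraction of query scores strictly above the ref q-quantile.

    The threshold is the linear-interpolation quantile of the reference
    scores; exceedance is strict (``>``) so exact ties with an interpolated
    threshold are excluded.
    """
    ref_scores = np.asarray(ref_scores, dtype=float)
    query_scores = np.asarray(query_scores, dtype=float)
    if not (0.0 < q < 1.0):
        raise ValidationError("tail quantile must lie in (0,1)")
    if ref_scores.size == 0:
        raise ValidationError("empty reference score vector")
    if query_scores.size == 0:
        raise ValidationError("empty query score vector")
    threshold = float(np.quantile(ref_scores, q))
    k = int((query_scores > threshold).sum())
    return {
        "tail_threshold": threshold,
        "tail_fraction": k / query_scores.size,
        "k_exceed": k,
        "n_query": int(query_scores.size),
    }


def binomial_tail_test(k_exceed: int, n_query: int, p0: float) -> float:
    """One-sided upper-tail P(X >= k) for X ~ Binomial(n, p0)."""
    if not (0 <= k_exceed <= n_query) or n_query <= 0:
        raise ValidationError(f"invalid counts k={k_exceed}, n={n_query}")
    if not (0.0 < p0 < 1.0):
        raise ValidationError("p0 must lie in (0,1)")
    if k_exceed == 0:
        return 1.0
    return float(binom.sf(k_exceed - 1, n_query, p0))


def permutation_tail_test(
    ref_scores: np.ndarray,
    query_scores: np.ndarray,
    q: float,
    n_permutations: int,
    seed: int,
) -> float:
    """Permutation p-value for tail enrichment within one cluster.

    Pooled scores are relabeled uniformly at random ``B`` times preserving
    group sizes; each permutation recomputes both the reference quantile and
    the query tail fraction. The add-one estimator
    ``p = (1 + #{perm >= obs}) / (1 + B)`` avoids zero p-values.
    """
    ref_scores = np.asarray(ref_scores, dtype=float)
    query_scores = np.asarray(query_scores, dtype=float)
    if n_permutations < 100:
        raise ValidationError("need at least 100 permutations")
    obs = tail_enrichment(ref_scores, query_scores, q)["tail_fraction"]

    pooled = np.concatenate([ref_scores, query_scores])
    if np.all(pooled == pooled[0]):
        logger.warning("degenerate pooled score vector (all identical); p = 1")
        return 1.0

    rng = np.random.default_rng(seed)
    n_ref = ref_scores.size
    perm = rng.permuted(
        np.broadcast_to(pooled, (n_permutations, pooled.size)).copy(), axis=1
    )
    thresholds = np.quantile(perm[:, :n_ref], q, axis=1)
    fracs = (perm[:, n_ref:] > thresholds[:, None]).mean(axis=1)
    return float((1 + int((fracs >= obs).sum())) / (1 + n_permutations))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j >= i} m * p_(j) / j on the ascending sort, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("bh_fdr needs a nonempty 1-d vector")
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def summarize_clusters(
    oor: OORResult, metadata: CellMetadata, config: RunConfig
) -> tuple[list[ClusterSummary], list[str]]:
    """Per-cluster summaries with BH-corrected q-values.

    Returns ``(summaries, skipped)`` where ``skipped`` lists clusters that
    lacked either reference or query cells (reported in the manifest).
    Without a configured cluster column all cells form one pseudo-cluster
    named ``"all"``.
    """
    ref_cfg = config.reference
    enr = config.enrichment
    cond = metadata.column(ref_cfg.condition_column).astype(str)
    ref_mask = cond == str(ref_cfg.reference_level)

    if ref_cfg.cluster_column is not None:
        clusters = metadata.column(ref_cfg.cluster_column).astype(str)
    else:
        clusters = np.full(len(oor.cell_ids), "all", dtype=object)

    scores = oor.oor
    fallback = np.asarray(oor.fallback_used, dtype=bool)
    summaries: list[ClusterSummary] = []
    skipped: list[str] = []
    for c in sorted(np.unique(clusters).tolist()):
        sel = clusters == c
        ref_s = scores[sel & ref_mask]
        qry_s = scores[sel & ~ref_mask]
        if ref_s.size == 0 or qry_s.size == 0:
            skipped.append(str(c))
            continue
        tail = tail_enrichment(ref_s, qry_s, enr.quantile)
        if enr.test == "binomial":
            if enr.in_sample_p0:
                p0 = float((ref_s > tail["tail_threshold"]).mean())
                p0 = min(max(p0, _TINY_P), 1.0 - 1e-12)
            else:
                p0 = 1.0 - enr.quantile
            p_val = binomial_tail_test(tail["k_exceed"], tail["n_query"], p0)
        else:
            p_val = permutation_tail_test(
                ref_s, qry_s, enr.quantile, enr.n_permutations, enr.seed
            )
        p_val = max(p_val, _TINY_P)  # keep inside (0,1] for BH
        summaries.append(
            ClusterSummary(
                cluster=str(c),
                n_ref=int(ref_s.size),
                n_query=int(qry_s.size),
                median_ref=float(np.median(ref_s)),
                median_query=float(np.median(qry_s)),
                median_shift=median_shift(ref_s, qry_s),
                tail_quantile=enr.quantile,
                tail_threshold=tail["tail_threshold"],
                tail_fraction=tail["tail_fraction"],
                expected_fraction=1.0 - enr.quantile,
                p_value=p_val,
                q_value=np.nan,  # filled below
                test=enr.test,
                fallback_used=bool(fallback[sel].any()),
            )
        )
    if not summaries:
        raise ValidationError(
            "no cluster contains both reference and query cells"
        )
    q_vals = bh_fdr([s.p_value for s in summaries])
    for s, qv in zip(summaries, q_vals):
        s.q_value = float(qv)
    return summaries, skipped
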