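"""Cluster-conditional reference distributions and out-of-reference scores.

A reference model stores, per cluster, the mean vector and shrunk
covariance of the uncertainty features of *reference* (control) cells.
Every cell is then scored by its squared Mahalanobis distance

    OOR(x) = (x - mu)^T Sigma^{-1} (x - mu)

against its cluster's statistics, with a global fallback for clusters
holding fewer than ``min_cells`` reference cells (covariance estimation is
unreliable there). Covariances are shrunk toward their diagonal,

    Sigma_shrunk = (1 - lambda) * Sigma + lambda * diag(Sigma) + eps * I,

with lambda = 0.1 by default; the epsilon ridge guards exactly-degenerate
coordinates (a constant feature in some reference subset), which shrinkage
alone cannot fix. Shrinkage is applied uniformly to the global and every
per-cluster covariance. Reference cells are scored in-sample (against
statistics that include themselves); this small optimism is deliberate —
the reference score distribution serves as the empirical null downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .features import FeatureTable
from .io import CellMetadata, RunConfig, ValidationError

GLOBAL_KEY = "global"


class SingularCovarianceError(ValueError):
    """Reference covariance is not positive definite."""


@dataclass
class ClusterStats:
    mean: np.ndarray
    cov: np.ndarray
    n_ref: int
    fallback_used: bool


@dataclass
class ReferenceModel:
    feature_names: tuple[str, ...]
    global_mean: np.ndarray
    global_cov: np.ndarray
    per_cluster: dict[str, ClusterStats] = field(default_factory=dict)
    min_cells: int = 50
    shrinkage_lambda: float = 0.1
    ridge_epsilon: float = 1e-8

    @property
    def d(self) -> int:
        return len(self.feature_names)

    def stats_for(self, cluster: str | None) -> tuple[np.ndarray, np.ndarray, str, bool]:
        """Return (mean, cov, cluster_used, fallback_used) for one cell."""
        if cluster is None:
            return self.global_mean, self.global_cov, GLOBAL_KEY, False
        st = self.per_cluster.get(cluster)
        if st is None:
            return self.global_mean, self.global_cov, GLOBAL_KEY, True
        if st.fallback_used:
            return self.global_mean, self.global_cov, cluster, True
        return st.mean, st.cov, cluster, False

    def to_dict(self) -> dict:
        """JSON-serializable audit dump of all stored statistics."""
        return {
            "feature_names": list(self.feature_names),
            "min_cells": self.min_cells,
            "shrinkage_lambda": self.shrinkage_lambda,
            "ridge_epsilon": self.ridge_epsilon,
            "global": {
                "mean": self.global_mean.tolist(),
                "cov": self.global_cov.tolist(),
            },
            "clusters": {
                c: {
                    "mean": st.mean.tolist(),
                    "cov": st.cov.tolist(),
                    "n_ref": st.n_ref,
                    "fallback_used": st.fallback_used,
                }
                for c, st in self.per_cluster.items()
            },
        }


@dataclass
class OORResult:
    cell_ids: list[str]
    oor: np.ndarray
    cluster_used: list[str]
    fallback_used: np.ndarray  # bool per cell


def shrink_covariance(cov: np.ndarray, lam: float, epsilon: float = 0.0) -> np.ndarray:
    """Shrink a covariance toward its diagonal and add a ridge."""
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValidationError("covariance must be a square matrix")
    if not np.allclose(cov, cov.T, atol=1e-9, rtol=0.0):
        raise ValidationError("covariance must be symmetric (tolerance 1e-9)")
    if not (0.0 <= lam <= 1.0):
        raise ValidationError("shrinkage lambda must lie in [0,1]")
    if epsilon < 0:
        raise ValidationError("ridge epsilon must be >= 0")
    d = cov.shape[0]
    out = (1.0 - lam) * cov + lam * np.diag(np.diag(cov)) + epsilon * np.eye(d)
    return 0.5 * (out + out.T)  # re-symmetrize against fp drift


def _check_pd(cov: np.ndarray, what: str):
    try:
        factor = cho_factor(cov, lower=True)
    except LinAlgError as exc:
        raise SingularCovarianceError(
            f"{what} covariance is not positive definite; increase "
            "ridge_epsilon or shrinkage_lambda"
        ) from exc
    # Cholesky can "succeed" on numerically singular input (pivot ~ 1e-15);
    # the squared diagonal ratio bounds the relative eigenvalue spread
    diag = np.abs(np.diag(factor[0]))
    if (diag.min() / diag.max()) ** 2 < 1e-12:
        raise SingularCovarianceError(
            f"{what} covariance is numerically singular (condition > 1e12); "
            "increase ridge_epsilon or shrinkage_lambda"
        )
    return factor


def fit_reference(
    features: FeatureTable, metadata: CellMetadata, config: RunConfig
) -> ReferenceModel:
    """Fit global and per-cluster reference statistics from control cells.

    Covariances use the n-1 denominator and are shrunk per the config.
    Clusters with fewer than ``min_cells`` reference cells are flagged and
    fall back to the global statistics.
    """
    ref_cfg = config.reference
    names = tuple(config.features)
    if len(names) == 0:
        raise ValidationError("empty feature subset")
    x = features.matrix(names)
    d = x.shape[1]

    cond = metadata.column(ref_cfg.condition_column).astype(str)
    ref_mask = cond == str(ref_cfg.reference_level)
    n_ref = int(ref_mask.sum())
    if n_ref == 0:
        raise ValidationError(
            f"no reference cells: no row of {ref_cfg.condition_column!r} equals "
            f"{ref_cfg.reference_level!r}"
        )
    if n_ref < d + 2:
        raise ValidationError(
            f"need at least d+2={d + 2} reference cells globally, found {n_ref}"
        )

    xr = x[ref_mask]
    global_mean = xr.mean(axis=0)
    global_cov = shrink_covariance(
        np.cov(xr, rowvar=False, ddof=1).reshape(d, d),
        ref_cfg.shrinkage_lambda,
        ref_cfg.ridge_epsilon,
    )
    _check_pd(global_cov, "global")

    model = ReferenceModel(
        feature_names=names,
        global_mean=global_mean,
        global_cov=global_cov,
        min_cells=ref_cfg.min_cells,
        shrinkage_lambda=ref_cfg.shrinkage_lambda,
        ridge_epsilon=ref_cfg.ridge_epsilon,
    )

    if ref_cfg.cluster_column is not None:
        clusters = metadata.column(ref_cfg.cluster_column).astype(str)
        for c in sorted({str(v) for v in clusters[ref_mask]}):
            sel = ref_mask & (clusters == c)
            n_c = int(sel.sum())
            if n_c < ref_cfg.min_cells:
                model.per_cluster[c] = ClusterStats(
                    mean=global_mean, cov=global_cov, n_ref=n_c, fallback_used=True
                )
                continue
            xc = x[sel]
            cov_c = shrink_covariance(
                np.cov(xc, rowvar=False, ddof=1).reshape(d, d),
                ref_cfg.shrinkage_lambda,
                ref_cfg.ridge_epsilon,
            )
            _check_pd(cov_c, f"cluster {c!r}")
            model.per_cluster[c] = ClusterStats(
                mean=xc.mean(axis=0), cov=cov_c, n_ref=n_c, fallback_used=False
            )
    return model


def oor_score(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Squared Mahalanobis distance via a Cholesky solve (no explicit inverse)."""
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    factor = _check_pd(np.asarray(cov, dtype=float), "supplied")
    diff = x - mean
    return float(diff @ cho_solve(factor, diff))


def _score_block(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    factor = _check_pd(cov, "reference")
    diff = x - mean
    return np.einsum("ij,ij->i", diff, cho_solve(factor, diff.T).T)


def score_all(
    features: FeatureTable, model: ReferenceModel, metadata: CellMetadata | None = None,
    cluster_column: str | None = None,
) -> OORResult:
    """Score every cell against its cluster's reference statistics.

    Cells in clusters absent from the model are scored against the global
    statistics with the fallback flag set (and a warning).
    """
    import logging

    x = features.matrix(model.feature_names)
    n = x.shape[0]
    oor = np.empty(n, dtype=float)
    cluster_used = np.empty(n, dtype=object)
    fallback = np.zeros(n, dtype=bool)

    if cluster_column is None or metadata is None:
        oor[:] = _score_block(x, model.global_mean, model.global_cov)
        cluster_used[:] = GLOBAL_KEY
    else:
        clusters = metadata.column(cluster_column).astype(str)
        unseen = sorted(set(clusters) - set(model.per_cluster))
        if unseen:
            logging.getLogger("oorkit").warning(
                "cluster(s) absent from the reference model scored globally: %s",
                ", ".join(unseen),
            )
        for c in np.unique(clusters):
            sel = clusters == c
            mean, cov, used, fb = model.stats_for(str(c))
            oor[sel] = _score_block(x[sel], mean, cov)
            cluster_used[sel] = used
            fallback[sel] = fb

    # guard tiny negative values from fp cancellation at the mean
    oor = np.where(oor < 0, 0.0, oor)
    return OORResult(
        cell_ids=list(features.cell_ids),
        oor=oor,
        cluster_used=list(cluster_used),
        fallback_used=fallback,
    )
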