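import numpy as np
import pandas as pd
import pytest

from oorkit.features import FeatureTable
from oorkit.io import CellMetadata, RunConfig, ValidationError
from oorkit.reference import (
    SingularCovarianceError,
    fit_reference,
    oor_score,
    score_all,
    shrink_covariance,
)


def make_table(X, ids=None):
    ids = ids or [f"c{i}" for i in range(len(X))]
    return FeatureTable.from_arrays(
        ids, P1=X[:, 0], delta=X[:, 1], admixture=X[:, 2], entropy=X[:, 3]
    )


def make_metadata(ids, condition, cluster=None):
    cols = {"condition": condition}
    if cluster is not None:
        cols["cluster"] = cluster
    return CellMetadata(list(ids), pd.DataFrame(cols, index=list(ids)))


def gaussian_features(n, rng, mean=None, cov=None):
    mean = np.zeros(4) if mean is None else mean
    cov = np.eye(4) if cov is None else cov
    return mean + rng.normal(size=(n, 4)) @ np.linalg.cholesky(cov).T


class TestShrinkCovariance:
    def test_hand_example(self):
        out = shrink_covariance(np.array([[1.0, 0.8], [0.8, 1.0]]), 0.1, 0.0)
        np.testing.assert_allclose(out, [[1.0, 0.72], [0.72, 1.0]], atol=1e-15)

    def test_identity_limit(self):
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        np.testing.assert_array_equal(shrink_covariance(cov, 0.0, 0.0), cov)

    def test_full_shrinkage_limit(self):
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        np.testing.assert_array_equal(shrink_covariance(cov, 1.0, 0.0), np.diag([2.0, 1.0]))

    def test_ridge_added_to_diagonal(self):
        out = shrink_covariance(np.eye(2), 0.0, 1e-3)
        np.testing.assert_allclose(np.diag(out), 1.001)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            shrink_covariance(np.array([[1.0, 0.5], [0.2, 1.0]]), 0.1)

    def test_lambda_bounds(self):
        with pytest.raises(ValidationError):
            shrink_covariance(np.eye(2), 1.5)


class TestOORScore:
    def test_zero_at_mean(self):
        assert oor_score(np.ones(4), np.ones(4), np.eye(4)) == 0.0

    def test_identity_covariance_is_squared_euclidean(self):
        x = np.array([1.0, 0.0, 0.0, 0.0])
        assert oor_score(x, np.zeros(4), np.eye(4)) == pytest.approx(1.0)

    def test_diagonal_inverse_by_hand(self):
        # 4/2 + 1/0.5 = 4
        val = oor_score(np.array([2.0, 1.0]), np.zeros(2), np.diag([2.0, 0.5]))
        assert val == pytest.approx(4.0, rel=1e-12)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            A = rng.normal(size=(4, 4))
            cov = A @ A.T + 0.1 * np.eye(4)
            x, mean = rng.normal(size=4), rng.normal(size=4)
            expected = (x - mean) @ np.linalg.inv(cov) @ (x - mean)
            assert oor_score(x, mean, cov) == pytest.approx(expected, rel=1e-8)

    def test_non_pd_rejected(self):
        with pytest.raises(SingularCovarianceError, match="ridge|shrink"):
            oor_score(np.ones(2), np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(4, 4))
        cov = A @ A.T + 0.1 * np.eye(4)
        x, mean = rng.normal(size=4), rng.normal(size=4)
        s = np.array([10.0, 0.1, 3.0, 1.0])
        scaled = oor_score(s * x, s * mean, cov * np.outer(s, s))
        assert scaled == pytest.approx(oor_score(x, mean, cov), rel=1e-9)


class TestFitReference:
    def _config(self, **ref):
        base = {"condition_column": "condition", "reference_level": "control"}
        base.update(ref)
        return RunConfig.from_dict({"reference": base})

    def test_fallback_boundary_49_vs_50(self):
        rng = np.random.default_rng(2)
        for n_a, expect_fallback in [(49, True), (50, False)]:
            n = n_a + 60
            X = gaussian_features(n, rng)
            ids = [f"c{i}" for i in range(n)]
            md = make_metadata(ids, ["control"] * n, ["A"] * n_a + ["B"] * 60)
            cfg = self._config(cluster_column="cluster", min_cells=50)
            model = fit_reference(make_table(X, ids), md, cfg)
            assert model.per_cluster["A"].fallback_used is expect_fallback
            assert model.per_cluster["B"].fallback_used is False
            if expect_fallback:
                np.testing.assert_array_equal(model.per_cluster["A"].mean, model.global_mean)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(3)
        true_mean = np.array([0.5, -1.0, 2.0, 0.0])
        A = rng.normal(size=(4, 4))
        true_cov = A @ A.T + 0.5 * np.eye(4)
        n = 5000
        X = gaussian_features(n, rng, true_mean, true_cov)
        ids = [f"c{i}" for i in range(n)]
        md = make_metadata(ids, ["control"] * n)
        cfg = self._config(shrinkage_lambda=0.0, ridge_epsilon=0.0)
        model = fit_reference(make_table(X, ids), md, cfg)
        se = np.sqrt(np.diag(true_cov) / n)
        assert np.all(np.abs(model.global_mean - true_mean) < 3 * se)
        scale = np.sqrt(np.outer(np.diag(true_cov), np.diag(true_cov)))
        assert np.all(np.abs(model.global_cov - true_cov) / scale < 0.10)

    def test_zero_reference_cells_rejected(self):
        X = np.random.default_rng(4).normal(size=(10, 4))
        ids = [f"c{i}" for i in range(10)]
        md = make_metadata(ids, ["case"] * 10)
        with pytest.raises(ValidationError, match="no reference cells"):
            fit_reference(make_table(X, ids), md, self._config())

    def test_too_few_reference_cells_rejected(self):
        X = np.random.default_rng(5).normal(size=(10, 4))
        ids = [f"c{i}" for i in range(10)]
        md = make_metadata(ids, ["control"] * 4 + ["case"] * 6)
        with pytest.raises(ValidationError, match="d\\+2"):
            fit_reference(make_table(X, ids), md, self._config())

    def test_degenerate_feature_needs_ridge(self):
        rng = np.random.default_rng(6)
        X = gaussian_features(100, rng)
        X[:, 3] = 0.7  # constant coordinate: zero variance
        ids = [f"c{i}" for i in range(100)]
        md = make_metadata(ids, ["control"] * 100)
        with pytest.raises(SingularCovarianceError):
            fit_reference(make_table(X, ids), md,
                          self._config(shrinkage_lambda=0.0, ridge_epsilon=0.0))
        model = fit_reference(make_table(X, ids), md,
                              self._config(shrinkage_lambda=0.0, ridge_epsilon=1e-8))
        assert np.linalg.eigvalsh(model.global_cov).min() > 0


class TestScoreAll:
    def _fit(self, X, md, **ref):
        base = {"condition_column": "condition", "reference_level": "control"}
        base.update(ref)
        cfg = RunConfig.from_dict({"reference": base})
        ids = list(md.cell_ids)
        return make_table(X, ids), fit_reference(make_table(X, ids), md, cfg), cfg

    def test_all_cells_at_mean_score_zero(self):
        rng = np.random.default_rng(7)
        X = gaussian_features(60, rng)
        ids = [f"c{i}" for i in range(60)]
        md = make_metadata(ids, ["control"] * 60)
        ft, model, _ = self._fit(X, md)
        at_mean = make_table(np.tile(model.global_mean, (5, 1)), [f"q{i}" for i in range(5)])
        res = score_all(at_mean, model)
        np.testing.assert_allclose(res.oor, 0.0, atol=1e-12)

    def test_single_cluster_equals_global(self):
        rng = np.random.default_rng(8)
        X = gaussian_features(120, rng)
        ids = [f"c{i}" for i in range(120)]
        md = make_metadata(ids, ["control"] * 80 + ["case"] * 40, ["only"] * 120)
        ft, model, cfg = self._fit(X, md, cluster_column="cluster", min_cells=50)
        res_cluster = score_all(ft, model, md, "cluster")
        res_global = score_all(ft, model)
        np.testing.assert_allclose(res_cluster.oor, res_global.oor, rtol=1e-9)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(9)
        X = gaussian_features(300, rng)
        ids = [f"c{i}" for i in range(300)]
        md = make_metadata(ids, ["control"] * 200 + ["case"] * 100)
        ft, model, cfg = self._fit(X, md, shrinkage_lambda=0.0, ridge_epsilon=0.0)
        base = score_all(ft, model).oor
        M = rng.normal(size=(4, 4)) + 4 * np.eye(4)  # invertible
        ft2 = make_table(X @ M.T, ids)
        model2 = fit_reference(ft2, md, cfg)
        np.testing.assert_allclose(score_all(ft2, model2).oor, base, rtol=1e-6)

    def test_unseen_cluster_scored_globally_with_flag(self, caplog):
        rng = np.random.default_rng(10)
        X = gaussian_features(120, rng)
        ids = [f"c{i}" for i in range(120)]
        md = make_metadata(
            ids, ["control"] * 100 + ["case"] * 20, ["A"] * 100 + ["mystery"] * 20
        )
        ft, model, _ = self._fit(X, md, cluster_column="cluster", min_cells=50)
        with caplog.at_level("WARNING", logger="oorkit"):
            res = score_all(ft, model, md, "cluster")
        assert "mystery" in caplog.text
        assert all(res.fallback_used[100:])
        assert set(res.cluster_used[100:]) == {"global"}

    def test_fallback_toggle_changes_only_that_cluster(self):
        rng = np.random.default_rng(11)
        nB, nq = 60, 30
        X_b = gaussian_features(nB, rng)
        X_q = gaussian_features(nq, rng)
        X_a49 = gaussian_features(49, rng)
        extra = gaussian_features(1, rng)

        def run(X_a):
            nA = len(X_a)
            X = np.vstack([X_a, X_b, X_q])
            ids = [f"c{i}" for i in range(len(X))]
            md = make_metadata(
                ids,
                ["control"] * (nA + nB) + ["case"] * nq,
                ["A"] * nA + ["B"] * nB + ["A"] * (nq // 2) + ["B"] * (nq - nq // 2),
            )
            ft, model, _ = self._fit(X, md, cluster_column="cluster", min_cells=50)
            res = score_all(ft, model, md, "cluster")
            # scores for the query block only (shared across both runs)
            return model, res.oor[nA + nB:]

        model49, q49 = run(X_a49)
        model50, q50 = run(np.vstack([X_a49, extra]))
        assert model49.per_cluster["A"].fallback_used is True
        assert model50.per_cluster["A"].fallback_used is False
        # B-cluster query scores identical; A-cluster query scores change
        nA_q = 15
        np.testing.assert_allclose(q49[nA_q:], q50[nA_q:], rtol=1e-12)
        assert not np.allclose(q49[:nA_q], q50[:nA_q])
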