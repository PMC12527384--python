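"""PCA, cross-distance, embedding/clustering and cluster characterization."""

import warnings

import numpy as np
import pandas as pd
import pytest

from trackpheno import heterogeneity as H
from trackpheno import stats as ST
from trackpheno.types import DistanceMatrix, FeatureTensor, TrackphenoWarning


def _tensor(values, names=None):
    n, t, f = values.shape
    return FeatureTensor(
        track_index=pd.MultiIndex.from_tuples(
            [("m1", "p1", i) for i in range(n)],
            names=["mouse_id", "position_id", "track_id"],
        ),
        time_grid=np.arange(t, dtype=float),
        feature_names=names or [f"f{j}" for j in range(f)],
        values=values,
    )


class TestScaleAndPca:
    def test_isotropic_features_need_all_pcs(self):
        # 5 independent equal-variance features: each PC carries ~20%
        rng = np.random.default_rng(42)
        tensor = _tensor(rng.normal(size=(100, 20, 5)))
        pcs = H.scale_and_pca(tensor, var_threshold=0.90)
        assert pcs.n_pc == 5
        assert np.allclose(pcs.explained_variance_ratio, 0.2, atol=0.02)

    def test_exact_linear_dependence_collapses_rank(self):
        rng = np.random.default_rng(43)
        x = rng.normal(size=(50, 10, 1))
        tensor = _tensor(np.concatenate([x, 2 * x], axis=2))
        pcs = H.scale_and_pca(tensor, var_threshold=0.99)
        assert pcs.n_pc == 1
        assert pcs.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_threshold_one_keeps_full_rank(self):
        rng = np.random.default_rng(44)
        tensor = _tensor(rng.normal(size=(30, 8, 4)))
        pcs = H.scale_and_pca(tensor, var_threshold=1.0)
        assert pcs.n_pc == 4

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(45)
        vals = rng.normal(size=(20, 5, 3))
        vals[:, :, 1] = 7.0
        with pytest.warns(TrackphenoWarning, match="constant"):
            pcs = H.scale_and_pca(_tensor(vals), var_threshold=1.0)
        assert pcs.n_pc == 2

    def test_standardization_gives_affine_invariance(self):
        # rescaling a feature by an affine map leaves the PC scores identical
        rng = np.random.default_rng(46)
        vals = rng.normal(size=(25, 6, 3))
        scaled = vals.copy()
        scaled[:, :, 0] = 100.0 * scaled[:, :, 0] - 7.0
        p1 = H.scale_and_pca(_tensor(vals), var_threshold=1.0)
        p2 = H.scale_and_pca(_tensor(scaled), var_threshold=1.0)
        assert np.allclose(np.abs(p1.pc_values), np.abs(p2.pc_values), atol=1e-8)


class TestCrossDistance:
    def test_duplicate_tracks_have_zero_distance(self):
        rng = np.random.default_rng(47)
        x = rng.normal(size=(1, 6, 2))
        y = rng.normal(size=(1, 6, 2))
        from trackpheno.types import PCSeries

        pcs = PCSeries(
            track_index=_tensor(np.zeros((3, 6, 2))).track_index,
            time_grid=np.arange(6, dtype=float),
            pc_values=np.concatenate([x, x, y]),
            explained_variance_ratio=np.array([0.6, 0.4]),
            n_pc=2,
        )
        dmat = H.cross_distance(pcs)
        assert dmat.D[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert dmat.D[0, 2] > 0

    def test_entries_match_pairwise_calls_and_symmetry(self):
        rng = np.random.default_rng(48)
        from trackpheno.types import PCSeries

        vals = rng.normal(size=(5, 7, 3))
        pcs = PCSeries(
            track_index=_tensor(np.zeros((5, 7, 3))).track_index,
            time_grid=np.arange(7, dtype=float),
            pc_values=vals,
            explained_variance_ratio=np.array([0.5, 0.3, 0.2]),
            n_pc=3,
        )
        dmat = H.cross_distance(pcs, step="symmetric1", window=3)
        for i in range(5):
            assert dmat.D[i, i] == 0.0
            for j in range(i + 1, 5):
                expect = H.dtw_distance(vals[i], vals[j], step="symmetric1", window=3)
                assert dmat.D[i, j] == pytest.approx(expect, abs=1e-12)
                assert dmat.D[j, i] == dmat.D[i, j]


class TestEmbedCluster:
    @staticmethod
    def _planted_distance(rng, n_per=12, k=3, sep=50.0):
        centers = np.arange(k)[:, None] * sep
        pts = np.concatenate([centers[i] + rng.normal(0, 1, size=(n_per, 1)) for i in range(k)])
        D = np.abs(pts - pts.T)
        np.fill_diagonal(D, 0.0)
        idx = pd.MultiIndex.from_tuples(
            [("m1", "p1", i) for i in range(k * n_per)],
            names=["mouse_id", "position_id", "track_id"],
        )
        truth = np.repeat(np.arange(k), n_per)
        return DistanceMatrix(idx, D), truth

    def test_recovers_separated_groups(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(49)
        dmat, truth = self._planted_distance(rng)
        res = H.embed_and_cluster(dmat, k=3, seed=42, n_neighbors=10)
        assert adjusted_rand_score(truth, res.labels) >= 0.9

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(50)
        dmat, _ = self._planted_distance(rng)
        r1 = H.embed_and_cluster(dmat, k=3, seed=7, n_neighbors=10)
        r2 = H.embed_and_cluster(dmat, k=3, seed=7, n_neighbors=10)
        assert np.array_equal(r1.labels, r2.labels)
        assert np.array_equal(r1.embedding, r2.embedding)

    def test_k_bounds_rejected(self):
        rng = np.random.default_rng(51)
        dmat, _ = self._planted_distance(rng, n_per=4)
        with pytest.raises(ValueError):
            H.embed_and_cluster(dmat, k=1)
        with pytest.raises(ValueError):
            H.embed_and_cluster(dmat, k=12)

    def test_pam_on_distances_recovers_groups(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(52)
        dmat, truth = self._planted_distance(rng)
        res = H.embed_and_cluster(dmat, k=3, seed=3, n_neighbors=10, cluster_on="distance")
        assert adjusted_rand_score(truth, res.labels) >= 0.9


class TestCharacterize:
    @staticmethod
    def _result(labels, k):
        n = len(labels)
        idx = pd.MultiIndex.from_tuples(
            [("m1", "p1", i) for i in range(n)],
            names=["mouse_id", "position_id", "track_id"],
        )
        from trackpheno.types import ClusterResult

        return ClusterResult(idx, np.zeros((n, 2)), np.asarray(labels), k=k)

    def test_rescaled_and_raw_means(self):
        res = self._result([0, 0, 1, 1], 2)
        summaries = pd.DataFrame({"mean_speed": [1.0, 1.0, 3.0, 3.0]}, index=res.track_index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", TrackphenoWarning)
            out = H.characterize_clusters(res, summaries).set_index("cluster")
        assert out.loc[0, "mean"] == pytest.approx(1.0)
        assert out.loc[1, "mean"] == pytest.approx(3.0)
        assert out.loc[0, "scaled_mean"] == pytest.approx(0.0)
        assert out.loc[1, "scaled_mean"] == pytest.approx(1.0)

    def test_constant_feature_degenerate(self):
        res = self._result([0, 0, 1, 1], 2)
        summaries = pd.DataFrame({"mean_speed": [2.0, 2.0, 2.0, 2.0]}, index=res.track_index)
        with pytest.warns(TrackphenoWarning, match="degenerate"):
            out = H.characterize_clusters(res, summaries)
        assert (out["scaled_mean"] == 0).all()
        assert out["anova_p"].isna().all()

    def test_anova_p_matches_stats_module(self):
        rng = np.random.default_rng(53)
        labels = np.repeat([0, 1, 2], 10)
        vals = rng.normal(size=30) + labels * 0.5
        res = self._result(labels, 3)
        summaries = pd.DataFrame({"f": vals}, index=res.track_index)
        out = H.characterize_clusters(res, summaries)
        expect = ST.one_way_anova({c: vals[labels == c] for c in range(3)}).pvalue
        assert np.allclose(out["anova_p"], expect)

    def test_singleton_cluster_excluded_from_anova(self):
        res = self._result([0, 0, 0, 1, 1, 2], 3)
        summaries = pd.DataFrame(
            {"f": [1.0, 2.0, 3.0, 5.0, 6.0, 99.0]}, index=res.track_index
        )
        with pytest.warns(TrackphenoWarning, match="singleton"):
            out = H.characterize_clusters(res, summaries)
        assert np.isfinite(out["anova_p"]).all()
        assert out.set_index("cluster").loc[2, "mean"] == pytest.approx(99.0)
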