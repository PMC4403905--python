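import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, rankdata

from devtraj.io import SampleTable
from devtraj.trajectory import (
    centroids_and_gaps,
    correlation_cluster,
    mds_embed,
    pca_embed,
    spearman_distance,
)

from .conftest import make_samples


def expr_frame(vals, prefix="s"):
    vals = np.asarray(vals, dtype=float)
    return pd.DataFrame(
        vals,
        index=[f"g{i}" for i in range(vals.shape[0])],
        columns=[f"{prefix}{j}" for j in range(vals.shape[1])],
    )


class TestPCA:
    def test_duplicated_sample_same_coords(self):
        rng = np.random.default_rng(0)
        vals = rng.random((30, 5))
        vals = np.hstack([vals, vals[:, [2]]])  # s5 duplicates s2
        emb = pca_embed(expr_frame(vals))
        np.testing.assert_allclose(
            emb.coords.loc["s2"], emb.coords.loc["s5"], atol=1e-9
        )

    def test_matches_eigendecomposition_oracle(self):
        """Coords and variance fractions from a full eigendecomposition of
        the sample covariance, computed independently."""
        rng = np.random.default_rng(1)
        expr = expr_frame(rng.random((12, 4)) * 10)
        emb = pca_embed(expr)

        X = expr.to_numpy().T
        Xc = X - X.mean(axis=0)
        C = Xc @ Xc.T  # sample Gram matrix shares nonzero eigenvalues
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        oracle_coords = V[:, :2] * np.sqrt(w[:2])
        oracle_fracs = w[:2] / w.sum()

        np.testing.assert_allclose(
            np.abs(emb.coords.to_numpy()), np.abs(oracle_coords), atol=1e-9
        )
        np.testing.assert_allclose(emb.variance_fractions, oracle_fracs, atol=1e-9)
        assert emb.variance_fractions[0] >= emb.variance_fractions[1]
        assert sum(emb.variance_fractions) <= 1.0 + 1e-12

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(2)
        expr = expr_frame(rng.random((20, 6)))
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        e1 = pca_embed(expr)
        e2 = pca_embed(expr[perm])
        np.testing.assert_allclose(
            np.abs(e1.coords.loc[perm].to_numpy()),
            np.abs(e2.coords.to_numpy()),
            atol=1e-9,
        )

    def test_sign_convention_earliest_nonpositive(self):
        rng = np.random.default_rng(3)
        expr = expr_frame(rng.random((15, 4)))
        st = make_samples([0, 2, 4, 6], sample_ids=["s0", "s1", "s2", "s3"])
        emb = pca_embed(expr, st)
        assert emb.coords.loc["s0", "dim1"] <= 0
        assert emb.coords.loc["s0", "dim2"] <= 0

    def test_rank_deficient_rejected(self):
        expr = expr_frame(np.outer(np.arange(1, 6), [1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="rank"):
            pca_embed(expr)


class TestSpearmanDistance:
    def test_identical_and_antimonotone(self):
        base = np.arange(10, dtype=float)
        expr = expr_frame(np.column_stack([base, base, base[::-1]]))
        d = spearman_distance(expr)
        assert d.loc["s0", "s1"] == pytest.approx(0.0, abs=1e-12)
        # perfect anti-monotone: rho = -1, 1 - |rho| = 0
        assert d.loc["s0", "s2"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(4)
        expr = expr_frame(rng.random((40, 5)))
        d = spearman_distance(expr)
        for a in expr.columns:
            for b in expr.columns:
                rho = pearsonr(rankdata(expr[a]), rankdata(expr[b])).statistic
                assert d.loc[a, b] == pytest.approx(1 - abs(rho), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        expr = expr_frame(rng.random((30, 4)))
        warped = expr.copy()
        warped["s1"] = np.exp(3 * warped["s1"])  # strictly monotone per sample
        warped["s2"] = warped["s2"] ** 3
        pd.testing.assert_frame_equal(
            spearman_distance(expr), spearman_distance(warped)
        )

    def test_constant_profile_rejected(self):
        expr = expr_frame([[1.0, 5.0], [1.0, 2.0], [1.0, 9.0]])
        with pytest.raises(ValueError, match="s0"):
            spearman_distance(expr)


class TestMDS:
    def test_equilateral_triangle(self):
        d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        emb = mds_embed(d)
        dd = pdist(emb.coords.to_numpy())
        np.testing.assert_allclose(dd, dd[0], atol=1e-6)

    def test_planted_2d_configuration_recovered(self):
        """Distances that are exactly Euclidean in 2-D embed at ~zero stress."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(9, 2))
        ids = [f"p{i}" for i in range(9)]
        d = pd.DataFrame(squareform(pdist(X)), index=ids, columns=ids)
        emb = mds_embed(d)
        assert emb.stress <= 1e-6
        np.testing.assert_allclose(
            squareform(pdist(emb.coords.to_numpy())), d.to_numpy(), atol=1e-5
        )

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        vals = rng.random((25, 6))
        d = spearman_distance(expr_frame(vals))
        e1, e2 = mds_embed(d, seed=1), mds_embed(d, seed=99)
        pd.testing.assert_frame_equal(e1.coords, e2.coords)

    def test_stress_monotone_and_below_start(self):
        rng = np.random.default_rng(8)
        vals = rng.random((40, 8))
        d = spearman_distance(expr_frame(vals))
        emb = mds_embed(d)
        trace = np.asarray(emb.stress_trace)
        assert np.all(np.diff(trace) <= 1e-12)
        assert emb.stress <= trace[0]


class TestGaps:
    def test_collinear_equal_spacing_no_leaps(self):
        st = make_samples([0, 1, 2, 3, 4])
        coords = pd.DataFrame(
            {"dim1": [0.0, 1, 2, 3, 4], "dim2": 0.0},
            index=st.df["sample_id"].tolist(),
        )
        from devtraj.trajectory import TrajectoryEmbedding

        emb = TrajectoryEmbedding(coords=coords, method="pca")
        gp = centroids_and_gaps(emb, st, "c")
        assert (gp.steps["label"] == "lull").all()

    def test_distances_match_euclidean_oracle_and_scale_invariance(self):
        rng = np.random.default_rng(9)
        st = make_samples([0, 1, 2, 4, 6], n_reps=2)
        coords = pd.DataFrame(
            rng.normal(size=(10, 2)),
            columns=["dim1", "dim2"],
            index=st.df["sample_id"].tolist(),
        )
        from devtraj.trajectory import TrajectoryEmbedding

        emb = TrajectoryEmbedding(coords=coords, method="mds")
        gp = centroids_and_gaps(emb, st, "c")
        # oracle: average replicate coords per time, consecutive distances
        times = [0, 1, 2, 4, 6]
        cent = np.array(
            [
                coords.loc[[f"c_{t:g}_r1", f"c_{t:g}_r2"]].mean(axis=0)
                for t in times
            ]
        )
        oracle = np.linalg.norm(np.diff(cent, axis=0), axis=1)
        np.testing.assert_allclose(gp.steps["distance"], oracle, atol=1e-12)
        # scaling all coords leaves labels unchanged
        emb2 = TrajectoryEmbedding(coords=coords * 37.5, method="mds")
        gp2 = centroids_and_gaps(emb2, st, "c")
        assert list(gp.steps["label"]) == list(gp2.steps["label"])

    def test_single_replicate_centroid_is_sample(self):
        st = make_samples([0, 1, 2])
        coords = pd.DataFrame(
            {"dim1": [1.0, 5.0, 2.0], "dim2": [0.0, 1.0, 3.0]},
            index=st.df["sample_id"].tolist(),
        )
        from devtraj.trajectory import TrajectoryEmbedding

        emb = TrajectoryEmbedding(coords=coords, method="pca")
        gp = centroids_and_gaps(emb, st, "c")
        assert gp.steps.loc[0, "distance"] == pytest.approx(np.hypot(4.0, 1.0))

    def test_too_few_time_points_rejected(self):
        st = make_samples([0, 1])
        coords = pd.DataFrame(
            {"dim1": [0.0, 1.0], "dim2": 0.0}, index=st.df["sample_id"].tolist()
        )
        from devtraj.trajectory import TrajectoryEmbedding

        emb = TrajectoryEmbedding(coords=coords, method="pca")
        with pytest.raises(ValueError, match="< 3 time points"):
            centroids_and_gaps(emb, st, "c")


class TestClustering:
    def test_two_stage_bipartition_high_support(self):
        """Two well-separated expression blocks: the bipartition gets >= 0.95
        bootstrap support at n_boot = 200."""
        rng = np.random.default_rng(10)
        n_genes = 150
        # independent rank structures (|Spearman| between stages ~ 0,
        # within stages ~ 1); a mirrored two-level pattern would be
        # ANTI-correlated, which 1 - |rho| treats as identical
        early = rng.lognormal(3, 1, n_genes)
        late = rng.lognormal(3, 1, n_genes)
        cols = {}
        for j in range(4):
            cols[f"e{j}"] = early * rng.lognormal(0, 0.05, n_genes)
        for j in range(4):
            cols[f"l{j}"] = late * rng.lognormal(0, 0.05, n_genes)
        expr = pd.DataFrame(cols)
        res = correlation_cluster(expr, n_boot=200, seed=0)
        early_set = frozenset(f"e{j}" for j in range(4))
        late_set = frozenset(f"l{j}" for j in range(4))
        assert res.support.get(early_set, 0.0) >= 0.95
        assert res.support.get(late_set, 0.0) >= 0.95

    def test_nboot_zero_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(0).random((10, 4)))
        with pytest.raises(ValueError, match="n_boot"):
            correlation_cluster(expr, n_boot=0)

    def test_average_linkage_heights_nondecreasing(self):
        rng = np.random.default_rng(11)
        expr = pd.DataFrame(rng.random((50, 7)))
        res = correlation_cluster(expr, n_boot=1, seed=0)
        heights = res.linkage_matrix[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)
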