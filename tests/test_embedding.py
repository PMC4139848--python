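"""PCA / classical MDS / Sammon / UKR embeddings and 2D accuracy."""

import numpy as np
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import cdist, pdist, squareform

import metaneighbor as mn
from metaneighbor.embedding import l1_kernel_pca_init


def _dm_from_points(pts, metric="euclidean", ids=None):
    ids = ids or tuple(f"S{i:03d}" for i in range(len(pts)))
    return mn.DistanceMatrix(tuple(ids), squareform(pdist(pts, metric)), metric)


def _planted_2d(n=30, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n, 2)) * [3.0, 1.0]


class TestPCA:
    def test_planar_data_explains_all_variance(self):
        rng = np.random.default_rng(1)
        plane = rng.normal(size=(25, 2)) @ rng.normal(size=(2, 10))
        coll = mn.ProfileCollection(
            tuple(f"S{i}" for i in range(25)),
            tuple(f"F{j}" for j in range(10)),
            plane - plane.min(),
        )
        emb = mn.pca_embed(coll, 2)
        assert sum(emb.explained_variance) == pytest.approx(1.0, abs=1e-9)

    def test_full_rank_scores_preserve_distances(self):
        rng = np.random.default_rng(2)
        X = rng.random((6, 4)) * 10
        coll = mn.ProfileCollection(
            tuple("ABCDEF"), tuple(f"F{j}" for j in range(4)), X
        )
        emb = mn.pca_embed(coll, n_dims=4)
        np.testing.assert_allclose(
            pdist(emb.coords), pdist(X), atol=1e-8
        )

    def test_duplicate_rows_identical_coordinates(self):
        X = np.array([[1.0, 2.0, 3.0], [4.0, 0.0, 1.0], [1.0, 2.0, 3.0]])
        coll = mn.ProfileCollection(("A", "B", "A2"), ("f1", "f2", "f3"), X)
        emb = mn.pca_embed(coll)
        np.testing.assert_allclose(emb.coords[0], emb.coords[2], atol=1e-10)

    def test_n_dims_too_large_rejected(self, tiny_collection):
        with pytest.raises(ValueError, match="n_dims"):
            mn.pca_embed(tiny_collection, n_dims=5)


class TestClassicalMDS:
    def test_recovers_planted_configuration(self):
        pts = _planted_2d(n=30)
        emb = mn.mds_embed(_dm_from_points(pts))
        _, _, disparity = procrustes(pts, emb.coords)
        assert disparity < 1e-12

    def test_collinear_points_have_zero_second_coordinate(self):
        pts = np.c_[np.array([0.0, 1.0, 3.0, 7.0]), np.zeros(4)]
        emb = mn.mds_embed(_dm_from_points(pts))
        np.testing.assert_allclose(emb.coords[:, 1], 0.0, atol=1e-9)

    def test_all_zero_distances_collapse_to_origin(self):
        dm = mn.DistanceMatrix(("A", "B", "C"), np.zeros((3, 3)), "cityblock")
        emb = mn.mds_embed(dm)
        np.testing.assert_allclose(emb.coords, 0.0, atol=1e-12)

    def test_agrees_with_pcoa_oracle(self):
        """scikit-bio's PCoA is an independent classical-MDS implementation."""
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(3)
        pts = rng.random((12, 5))
        dm = _dm_from_points(pts, "cityblock")
        emb = mn.mds_embed(dm)
        res = pcoa(dm.values, number_of_dimensions=2)
        ours = np.abs(emb.coords)  # sign conventions differ; compare magnitudes
        theirs = np.abs(res.samples.to_numpy())
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_negative_eigenvalues_clamped_for_l1_input(self, random_collection):
        dm = mn.pairwise_distances(random_collection, "cityblock")
        emb = mn.mds_embed(dm)
        assert np.all(np.isfinite(emb.coords))
        assert all(v >= 0 for v in emb.explained_variance)


class TestSammon:
    def test_perfect_init_does_not_move(self):
        pts = _planted_2d(n=15)
        dm = _dm_from_points(pts)
        init = mn.Embedding(dm.sample_ids, pts, "mds")
        emb = mn.sammon_embed(dm, init=init)
        assert emb.trace[0] == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_allclose(emb.coords, pts)

    def test_stress_never_exceeds_mds_initialization(self, random_collection):
        dm = mn.pairwise_distances(random_collection, "cityblock")
        emb = mn.sammon_embed(dm)
        assert emb.trace[-1] <= emb.trace[0]

    def test_realizable_instance_converges_to_tiny_stress(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        dm = _dm_from_points(pts)
        # start away from the solution to force actual optimization
        init = mn.Embedding(dm.sample_ids, pts * 1.7 + 0.3, "mds")
        emb = mn.sammon_embed(dm, init=init, max_iter=2000, tol=1e-15)
        assert emb.trace[-1] < 1e-6

    def test_trace_is_non_increasing(self, random_collection):
        dm = mn.pairwise_distances(random_collection, "cityblock")
        emb = mn.sammon_embed(dm)
        assert np.all(np.diff(emb.trace) <= 0)

    def test_duplicate_samples_colocate(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0], [6.0, 0.0]])
        dm = _dm_from_points(pts)
        emb = mn.sammon_embed(dm, max_iter=500)
        d01 = np.linalg.norm(emb.coords[0] - emb.coords[1])
        assert d01 < 1e-3


class TestL1KernelPCA:
    def test_duplicate_rows_identical_init(self):
        X = np.array([[1.0, 2.0], [5.0, 1.0], [1.0, 2.0], [0.0, 4.0]])
        coll = mn.ProfileCollection(("A", "B", "A2", "C"), ("f1", "f2"), X)
        emb = l1_kernel_pca_init(coll)
        np.testing.assert_allclose(emb.coords[0], emb.coords[2], atol=1e-10)

    def test_output_is_centered(self, random_collection):
        emb = l1_kernel_pca_init(random_collection)
        np.testing.assert_allclose(emb.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_agrees_with_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(4)
        X = rng.random((6, 5))
        coll = mn.ProfileCollection(
            tuple("ABCDEF"), tuple(f"F{j}" for j in range(5)), X
        )
        emb = l1_kernel_pca_init(coll)
        # oracle: explicit centered kernel matrix and numpy eig magnitudes
        D = cdist(X, X, "cityblock")
        s = np.median(D[~np.eye(6, dtype=bool)])
        K = np.exp(-D / s)
        H = np.eye(6) - np.ones((6, 6)) / 6
        w, V = np.linalg.eigh(H @ K @ H)
        idx = np.argsort(w)[::-1][:2]
        oracle = V[:, idx] * np.sqrt(w[idx])
        np.testing.assert_allclose(np.abs(emb.coords), np.abs(oracle), atol=1e-9)


class TestUKR:
    def test_objective_never_exceeds_initialization(self, random_collection):
        emb = mn.ukr_embed(random_collection, max_iter=60)
        assert emb.trace[-1] <= emb.trace[0]
        assert np.all(np.diff(emb.trace) <= 0)

    def test_gradient_matches_finite_differences(self):
        from metaneighbor.embedding import _ukr_objective_grad

        rng = np.random.default_rng(5)
        Y = rng.random((7, 4))
        X = rng.normal(size=(7, 2))
        ids = tuple(f"S{i}" for i in range(7))
        R, grad = _ukr_objective_grad(X, Y, ids)
        eps = 1e-7
        for i in (0, 3, 6):
            for q in (0, 1):
                Xp = X.copy()
                Xp[i, q] += eps
                Rp, _ = _ukr_objective_grad(Xp, Y, ids)
                fd = (Rp - R) / eps
                assert grad[i, q] == pytest.approx(fd, abs=1e-4, rel=1e-3)

    def test_identical_rows_reconstruct_identically(self):
        Y = np.array([[2.0, 1.0, 0.0], [2.0, 1.0, 0.0], [0.0, 3.0, 1.0], [1.0, 0.0, 4.0]])
        coll = mn.ProfileCollection(("A", "A2", "B", "C"), ("f1", "f2", "f3"), Y)
        emb = mn.ukr_embed(coll, max_iter=50)
        X = emb.coords
        spread = np.abs(X).max()
        np.testing.assert_allclose(X[0], X[1], atol=1e-4 * spread)
        # leave-one-out Nadaraya-Watson reconstructions of the twins agree
        B = np.exp(-np.abs(X[:, None, :] - X[None, :, :]).sum(-1))
        np.fill_diagonal(B, 0.0)
        F = (B @ Y) / B.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(F[0], F[1], atol=1e-4)

    def test_curve_recovery_beats_pca_initialization(self):
        """Data on a smooth 1D curve in 20D: UKR lowers the LOO error below
        the kernel-PCA start by an actual optimization margin."""
        from metaneighbor.embedding import _ukr_objective_grad

        t = np.linspace(0, 1, 40)
        rng = np.random.default_rng(6)
        basis = rng.normal(size=(3, 20))
        Y = (np.c_[np.sin(2 * np.pi * t), np.cos(2 * np.pi * t), t**2] @ basis) + 5.0
        coll = mn.ProfileCollection(
            tuple(f"S{i:02d}" for i in range(40)),
            tuple(f"F{j:02d}" for j in range(20)),
            Y,
        )
        emb = mn.ukr_embed(coll, max_iter=200)
        assert emb.trace[-1] < emb.trace[0] * 0.99


class TestEmbeddingAccuracy:
    def test_separated_clusters_are_perfect(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.random((10, 2)), rng.random((10, 2)) + 50.0])
        emb = mn.Embedding(tuple(f"S{i}" for i in range(20)), pts, "pca")
        rep = mn.embedding_accuracy(emb, ["a"] * 10 + ["b"] * 10, k=5)
        assert rep.overall_accuracy == 1.0

    def test_shuffled_labels_approach_class_prior(self):
        rng = np.random.default_rng(8)
        n = 400
        pts = rng.random((n, 2))
        labels = [str(l) for l in rng.integers(0, 5, size=n)]
        rep = mn.embedding_accuracy(
            mn.Embedding(tuple(f"S{i:03d}" for i in range(n)), pts, "pca"),
            labels,
            k=10,
        )
        se = rep.per_sample_accuracy.std(ddof=1) / np.sqrt(n)
        assert abs(rep.overall_accuracy - 0.2) < 3 * se + 0.01

    def test_identical_to_explicit_metric_pipeline(self):
        rng = np.random.default_rng(9)
        pts = rng.random((15, 2))
        ids = tuple(f"S{i}" for i in range(15))
        labels = ["a", "b", "c"] * 5
        emb = mn.Embedding(ids, pts, "mds")
        via_emb = mn.embedding_accuracy(emb, labels, k=4)
        coll = mn.ProfileCollection(ids, ("x", "y"), pts)
        dm = mn.pairwise_distances(coll, "euclidean")
        via_modules = mn.loocv_accuracy(dm, labels, k=4)
        assert via_emb.overall_accuracy == via_modules.overall_accuracy
        np.testing.assert_array_equal(
            via_emb.per_sample_accuracy, via_modules.per_sample_accuracy
        )

    def test_permutation_invariance_of_method_pipeline(self, random_collection):
        dm = mn.pairwise_distances(random_collection, "cityblock")
        emb = mn.mds_embed(dm)
        rep = mn.embedding_accuracy(emb, random_collection.labels, k=3)
        perm = np.random.default_rng(10).permutation(random_collection.n_samples)
        shuffled = random_collection.subset(perm)
        emb_p = mn.mds_embed(mn.pairwise_distances(shuffled, "cityblock"))
        rep_p = mn.embedding_accuracy(emb_p, shuffled.labels, k=3)
        acc = dict(zip(rep.sample_ids, rep.per_sample_accuracy))
        acc_p = dict(zip(rep_p.sample_ids, rep_p.per_sample_accuracy))
        assert acc == pytest.approx(acc_p)


class TestEmbeddingIO:
    def test_writer_produces_readable_table(self, tmp_path, random_collection):
        emb = mn.pca_embed(random_collection)
        path = tmp_path / "emb.tsv"
        mn.write_embedding(emb, path, labels=random_collection.labels)
        lines = path.read_text().splitlines()
        assert any(line.startswith("# method: pca") for line in lines)
        header = [l for l in lines if l.startswith("sample_id")][0]
        assert header.split("\t") == ["sample_id", "x", "y", "label"]
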