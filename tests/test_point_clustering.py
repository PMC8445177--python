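"""Step 1: farthest-first seeding, retraction, Lloyd k-means, membership."""

import itertools
import warnings

import numpy as np
import pytest

from fiberclust.fiber_model import Tractogram
from fiberclust.point_clustering import (
    DEFAULT_POSITIONS,
    KmeansConfig,
    kmeans_fit,
    kpp_init,
    fit_point_clusters,
    retract_centroids,
    select_k_elbow,
)

from conftest import random_fibers


def kpp_sequential(points, k, first):
    """Plain transcription of the farthest-first seeding loop (oracle)."""
    import math
    pts = [tuple(p) for p in points]
    C = [pts[first]]
    for _ in range(1, k):
        D = [min(math.dist(x, c) for c in C) for x in pts]
        C.append(pts[D.index(max(D))])
    return np.array(C)


class TestKppInit:
    def test_unique_maximin_on_line(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [10, 0, 0]], dtype=float)
        # find a seed whose first pick is point 0
        for seed in range(20):
            cents, chosen, _ = kpp_init(pts, 2, seed, return_trace=True)
            if chosen[0] == 0:
                assert chosen[1] == 2
                break
        else:
            pytest.fail("no seed picked point 0 first")

    def test_k_equals_n_exhausts_points(self, rng):
        pts = rng.normal(size=(8, 3))
        cents = kpp_init(pts, 8, seed=3)
        assert {tuple(c) for c in cents} == {tuple(p) for p in pts}

    def test_matches_sequential_transcription(self, rng):
        pts = rng.normal(size=(50, 3)) * 10
        cents, chosen, _ = kpp_init(pts, 5, seed=11, return_trace=True)
        assert np.allclose(cents, kpp_sequential(pts, 5, chosen[0]), atol=1e-12)

    def test_maximin_property_from_trace(self, rng):
        # at each selection the chosen point's min-distance-to-centroids is
        # the maximum over all points
        pts = rng.normal(size=(60, 3)) * 5
        _, chosen, traces = kpp_init(pts, 8, seed=2, return_trace=True)
        for sel, D in zip(chosen[1:], traces):
            assert D[sel] == pytest.approx(D.max())

    def test_k_exceeds_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kpp_init(rng.normal(size=(3, 3)), 4)

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(30, 3))
        assert np.array_equal(kpp_init(pts, 4, 9), kpp_init(pts, 4, 9))


class TestRetraction:
    def test_r_zero_identity(self, rng):
        c = rng.normal(size=(5, 3))
        assert np.allclose(retract_centroids(c, 0.0), c)

    def test_r_one_collapses_to_mean(self, rng):
        c = rng.normal(size=(5, 3))
        out = retract_centroids(c, 1.0)
        assert np.allclose(out, c.mean(axis=0))

    def test_worked_example(self):
        c = np.array([[0, 0, 0], [10, 0, 0]], dtype=float)
        out = retract_centroids(c, 0.05)
        assert np.allclose(out, [[0.25, 0, 0], [9.75, 0, 0]])

    @pytest.mark.parametrize("r", [-0.1, 1.5])
    def test_rate_out_of_range_rejected(self, r):
        with pytest.raises(ValueError):
            retract_centroids(np.zeros((2, 3)), r)


class TestKmeansFit:
    def two_blobs(self, rng, n=4):
        a = rng.normal(0, 0.3, size=(n, 3))
        b = rng.normal(0, 0.3, size=(n, 3)) + [30, 0, 0]
        return np.vstack([a, b]), np.array([0] * n + [1] * n)

    @pytest.mark.parametrize("init", ["random", "kpp", "kpp_retract"])
    def test_separated_blobs_recovered(self, rng, init):
        pts, truth = self.two_blobs(rng)
        _, labels = kmeans_fit(pts, KmeansConfig(k=2, init=init, seed=4))
        assert len(set(zip(truth, labels))) == 2  # same partition up to relabel

    def test_blob_partition_is_global_optimum(self, rng):
        # brute force over all 2-partitions of 8 points
        pts, _ = self.two_blobs(rng, n=4)
        cents, labels = kmeans_fit(pts, KmeansConfig(k=2, seed=0))
        cost = ((pts - cents[labels]) ** 2).sum()
        best = np.inf
        for mask in itertools.product([0, 1], repeat=8):
            mask = np.array(mask)
            if mask.all() or not mask.any():
                continue
            c0, c1 = pts[mask == 0].mean(0), pts[mask == 1].mean(0)
            cc = ((pts - np.where(mask[:, None], c1, c0)) ** 2).sum()
            best = min(best, cc)
        assert cost == pytest.approx(best)

    def test_identical_points_k1(self):
        pts = np.tile([(1.0, 2.0, 3.0)], (10, 1))
        cents, labels = kmeans_fit(pts, KmeansConfig(k=1))
        assert np.allclose(cents[0], (1, 2, 3))
        assert np.all(labels == 0)

    def test_k1_centroid_is_mean(self, rng):
        pts = rng.normal(size=(40, 3))
        cents, _ = kmeans_fit(pts, KmeansConfig(k=1, seed=5))
        assert np.allclose(cents[0], pts.mean(axis=0))

    def test_lloyd_monotone_inertia(self, rng):
        # within-cluster sum of squares never increases between iterations
        pts = rng.normal(size=(200, 3)) * 5

        inertias = []
        from fiberclust import point_clustering as pc
        orig = pc.cdist

        def spy(a, b):
            d = orig(a, b)
            inertias.append((d.min(axis=1) ** 2).sum())
            return d

        pc.cdist = spy
        try:
            kmeans_fit(pts, KmeansConfig(k=6, seed=1))
        finally:
            pc.cdist = orig
        assert all(b <= a + 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_no_empty_clusters(self, rng):
        # heavy duplication provokes empty clusters; repair must refill them
        pts = np.repeat(rng.normal(size=(3, 3)), 5, axis=0)
        for seed in range(10):
            _, labels = kmeans_fit(pts, KmeansConfig(k=5, init="random", seed=seed))
            assert len(set(labels)) == 5

    def test_retract_r0_equals_kpp(self, rng):
        pts = rng.normal(size=(100, 3)) * 10
        c1, l1 = kmeans_fit(pts, KmeansConfig(k=5, init="kpp", seed=8))
        c2, l2 = kmeans_fit(pts, KmeansConfig(k=5, init="kpp_retract", r=0.0, seed=8))
        assert np.array_equal(l1, l2) and np.allclose(c1, c2)

    def test_k_exceeds_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_fit(rng.normal(size=(3, 3)), KmeansConfig(k=5))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            KmeansConfig(k=0)
        with pytest.raises(ValueError):
            KmeansConfig(k=2, init="d2_sampling")
        with pytest.raises(ValueError):
            KmeansConfig(k=2, tol=1.0)


class TestFitPointClusters:
    def parallel_bundles(self, rng):
        # 2 parallel straight bundles of 2 fibers each, far apart
        from conftest import straight_fiber
        a = straight_fiber(origin=(0, 0, 0))
        b = straight_fiber(origin=(0, 50, 0))
        fibers = np.stack([a, a + 0.1, b, b + 0.1])
        return Tractogram(fibers)

    def test_columns_separate_bundles(self, rng):
        t = self.parallel_bundles(rng)
        m = fit_point_clusters(t, k_middle=2, k_other=2, seed=0)
        for j in range(5):
            col = m.labels[:, j]
            assert col[0] == col[1] and col[2] == col[3] and col[0] != col[2]

    def test_n_equals_k_gives_singletons(self, rng):
        t = Tractogram(random_fibers(rng, 4))
        m = fit_point_clusters(t, k_middle=4, k_other=4, seed=1)
        for j in range(5):
            assert len(set(m.labels[:, j])) == 4

    def test_same_seed_identical_matrix(self, rng):
        t = Tractogram(random_fibers(rng, 30))
        m1 = fit_point_clusters(t, k_middle=5, k_other=6, seed=42)
        m2 = fit_point_clusters(t, k_middle=5, k_other=6, seed=42)
        assert np.array_equal(m1.labels, m2.labels)
        assert m1.k_per_position == m2.k_per_position

    def test_k_clamped_with_warning_when_n_small(self, rng):
        t = Tractogram(random_fibers(rng, 5))
        with pytest.warns(UserWarning, match="clamping"):
            m = fit_point_clusters(t, k_middle=200, k_other=300, seed=0)
        assert m.k_per_position == (5, 5, 5, 5, 5)

    def test_position_out_of_range_rejected(self, rng):
        t = Tractogram(random_fibers(rng, 5))
        with pytest.raises(ValueError):
            fit_point_clusters(t, positions=(0, 4, 11, 18, 21))

    def test_middle_column_index(self, rng):
        t = Tractogram(random_fibers(rng, 5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_point_clusters(t, seed=0)
        assert m.positions == DEFAULT_POSITIONS
        assert m.middle_column() == 2


class TestElbow:
    def test_selects_blob_count(self, rng):
        # 6 tight, well-separated blobs: the inertia cliff sits at k=6
        centers = rng.uniform(-60, 60, size=(6, 3))
        while np.min(
            np.linalg.norm(centers[:, None] - centers[None], axis=-1)
            + np.eye(6) * 1e9
        ) < 30:
            centers = rng.uniform(-60, 60, size=(6, 3))
        pts = np.vstack([c + rng.normal(0, 0.5, size=(50, 3)) for c in centers])
        assert select_k_elbow(pts, candidates=range(2, 13), seed=0) == 6
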