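import math

import numpy as np
import pytest

from _oracles import random_diagram, wasserstein_exhaustive
from turingtda import (
    BarcodeSet,
    cluster,
    distance_matrix,
    node_distance,
    select_clustering,
    silhouette,
    wasserstein,
)
from turingtda.persistence import PersistenceDiagram


def _diag(pairs, degree=0):
    return PersistenceDiagram(degree=degree, pairs=tuple(pairs))


def _bset(node_id, *channel_pairs):
    b0u, b1u, b0v, b1v = channel_pairs
    return BarcodeSet(
        node_id=node_id,
        b0u=_diag(b0u, 0),
        b1u=_diag(b1u, 1),
        b0v=_diag(b0v, 0),
        b1v=_diag(b1v, 1),
    )


class TestWasserstein:
    def test_identity(self):
        d = _diag([(0, 2), (1, 5), (3, math.inf)])
        for q in (1.0, 2.0, math.inf):
            assert wasserstein(d, d, 2.0, q) == 0.0

    def test_single_point_to_empty_w22(self):
        assert wasserstein(_diag([(0, 2)]), _diag([]), 2, 2) == pytest.approx(
            math.sqrt(2)
        )

    def test_single_point_to_empty_bottleneck(self):
        assert wasserstein(
            _diag([(2, 3)]), _diag([]), math.inf, math.inf
        ) == pytest.approx(0.5)

    def test_mismatched_infinite_bars(self):
        assert wasserstein(_diag([(1, math.inf)]), _diag([]), 2, 2) == math.inf

    def test_infinite_bars_match_by_birth(self):
        d1 = _diag([(1, math.inf), (4, math.inf)])
        d2 = _diag([(2, math.inf), (4, math.inf)])
        assert wasserstein(d1, d2, 2, 2) == pytest.approx(1.0)
        assert wasserstein(d1, d2, 2, math.inf) == pytest.approx(1.0)

    @pytest.mark.parametrize("p", [1.0, 2.0, math.inf])
    @pytest.mark.parametrize("q", [1.0, 2.0, math.inf])
    def test_matches_exhaustive_oracle(self, p, q):
        rng = np.random.default_rng(42)
        for _ in range(30):
            d1 = random_diagram(rng, 4)
            d2 = random_diagram(rng, 4)
            ours = wasserstein(_diag(d1), _diag(d2), p, q)
            oracle = wasserstein_exhaustive(d1, d2, p, q)
            assert ours == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_metric_properties_on_random_diagrams(self):
        rng = np.random.default_rng(7)
        diags = [random_diagram(rng, 3) for _ in range(8)]
        for a in diags:
            for b in diags:
                dab = wasserstein(_diag(a), _diag(b), 2, 2)
                assert dab >= 0
                assert dab == pytest.approx(
                    wasserstein(_diag(b), _diag(a), 2, 2), rel=1e-12
                )
        for a in diags[:4]:
            for b in diags[:4]:
                for c in diags[:4]:
                    ab = wasserstein(_diag(a), _diag(b), 2, 2)
                    bc = wasserstein(_diag(b), _diag(c), 2, 2)
                    ac = wasserstein(_diag(a), _diag(c), 2, 2)
                    assert ac <= ab + bc + 1e-9

    def test_zero_iff_equal(self):
        d1 = _diag([(0, 2), (1, 3)])
        d2 = _diag([(0, 2), (1, 3.001)])
        assert wasserstein(d1, d2, 2, 2) > 0


class TestNodeDistance:
    def test_identity_all_variants(self):
        A = _bset(0, [(1, 6)], [(2, 4)], [(1, 9)], [])
        for variant in ("d1", "d2", "dinf"):
            assert node_distance(A, A, variant) == 0.0

    def test_channel_arithmetic(self):
        """Channel W values (1, 2, 0, 2) give d1=5, d2=3, dinf=2."""
        # point vs empty diagram: W_{2,2} = gap / sqrt(2)
        g = math.sqrt(2)
        A = _bset(0, [(0, 1 * g)], [(0, 2 * g)], [], [(0, 2 * g)])
        B = _bset(1, [], [], [], [])
        assert node_distance(A, B, "d1") == pytest.approx(5.0)
        assert node_distance(A, B, "d2") == pytest.approx(3.0)
        assert node_distance(A, B, "dinf") == pytest.approx(2.0)
        assert node_distance(A, B, "d2", literal_d2=True) == pytest.approx(5.0)

    def test_dinf_below_d1(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            A = _bset(0, *(random_diagram(rng, 3) for _ in range(4)))
            B = _bset(1, *(random_diagram(rng, 3) for _ in range(4)))
            assert node_distance(A, B, "dinf") <= node_distance(A, B, "d1") + 1e-12


class TestDistanceMatrix:
    def test_identical_nodes(self):
        A = _bset(0, [(1, 6)], [], [], [])
        B = _bset(1, [(1, 6)], [], [], [])
        D = distance_matrix([A, B])
        assert np.array_equal(D, np.zeros((2, 2)))

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(9)
        nodes = [
            _bset(i, *(random_diagram(rng, 3) for _ in range(4)))
            for i in range(8)
        ]
        D = distance_matrix(nodes)
        assert np.array_equal(D, D.T)
        assert np.all(np.diag(D) == 0)
        assert np.all(D >= 0)

    def test_triangle_inequality_d1(self):
        rng = np.random.default_rng(10)
        nodes = [
            _bset(i, *(random_diagram(rng, 3) for _ in range(4)))
            for i in range(6)
        ]
        D = distance_matrix(nodes, "d1")
        n = len(nodes)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, k] <= D[i, j] + D[j, k] + 1e-9


def _two_blobs(n=20, within=0.1, between=10.0, seed=0):
    rng = np.random.default_rng(seed)
    D = np.full((n, n), between)
    half = n // 2
    for i in range(n):
        for j in range(n):
            if (i < half) == (j < half):
                D[i, j] = within * rng.uniform(0.5, 1.0)
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    labels_true = np.array([0] * half + [1] * (n - half))
    return D, labels_true


class TestClustering:
    @pytest.mark.parametrize("link", ["single", "complete", "average"])
    def test_two_blobs_recovered(self, link):
        D, truth = _two_blobs()
        labels = cluster(D, link, 2)
        assert len(set(zip(labels, truth))) == 2  # exact partition

    def test_k_equals_n(self):
        D, _ = _two_blobs(6)
        assert sorted(cluster(D, "average", 6)) == [1, 2, 3, 4, 5, 6]

    def test_k_one(self):
        D, _ = _two_blobs(6)
        assert set(cluster(D, "average", 1)) == {1}

    def test_k_too_large(self):
        D, _ = _two_blobs(6)
        with pytest.raises(ValueError):
            cluster(D, "average", 7)


class TestSilhouette:
    def test_two_blobs_high_score(self):
        D, truth = _two_blobs()
        assert silhouette(D, truth) > 0.9

    def test_equidistant_points_score_zero(self):
        n = 6
        D = np.ones((n, n)) - np.eye(n)
        labels = np.array([1, 1, 1, 2, 2, 2])
        assert silhouette(D, labels) == pytest.approx(0.0)

    def test_duplicate_clusters_score_one(self):
        D = np.array(
            [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 0], [5, 5, 0, 0]], float
        )
        assert silhouette(D, np.array([1, 1, 2, 2])) == pytest.approx(1.0)

    def test_single_cluster_rejected(self):
        D, _ = _two_blobs(6)
        with pytest.raises(ValueError):
            silhouette(D, np.ones(6))


class TestSelectClustering:
    def test_two_blobs_selects_k2(self):
        D, truth = _two_blobs()
        res = select_clustering(D, k_range=range(2, 6))
        assert res.k == 2
        assert len(set(zip(res.labels, truth))) == 2

    def test_three_points_k2_exists(self):
        D = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], float)
        res = select_clustering(D, k_range=range(2, 3))
        assert len(np.unique(res.labels)) == 2

    def test_empty_k_range_rejected(self):
        D, _ = _two_blobs(6)
        with pytest.raises(ValueError):
            select_clustering(D, k_range=range(2, 2))

    def test_invariant_to_node_order(self):
        D, _ = _two_blobs(12, seed=4)
        perm = np.random.default_rng(5).permutation(12)
        res1 = select_clustering(D, k_range=range(2, 5))
        res2 = select_clustering(D[np.ix_(perm, perm)], k_range=range(2, 5))
        assert res1.k == res2.k
        # same partition after permuting back
        relabeled = np.empty(12, dtype=int)
        relabeled[perm] = res2.labels
        assert len(set(zip(res1.labels, relabeled))) == res1.k
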