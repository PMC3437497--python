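"""Graph metrics, density-matched binarization and Jaccard agreement."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scfc import netmetrics as nmx
from scfc.fc_measures import FCMatrix


def fw_oracle(adj: np.ndarray):
    """Floyd-Warshall distances, independent of the BFS implementation."""
    n = adj.shape[0]
    D = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        D = np.minimum(D, D[:, k : k + 1] + D[k : k + 1, :])
    return D


def clustering_oracle(adj: np.ndarray) -> float:
    """Brute-force triangle enumeration."""
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(adj[a, b] for a, b in itertools.combinations(nbrs, 2))
        vals.append(2 * links / (k * (k - 1)))
    return float(np.mean(vals))


def _fc(values: np.ndarray) -> FCMatrix:
    return FCMatrix(values=values, measure="correlation")


class TestBinarize:
    def test_keeps_top_k(self):
        v = np.zeros((4, 4))
        pairs = [(0, 1, 0.9), (0, 2, 0.8), (0, 3, 0.7), (1, 2, 0.3), (1, 3, 0.2), (2, 3, 0.1)]
        for i, j, val in pairs:
            v[i, j] = v[j, i] = val
        np.fill_diagonal(v, 1.0)
        bn = nmx.binarize_to_density(_fc(v), 0.5)
        assert bn.m == 3
        assert bn.adjacency[0, 1] and bn.adjacency[0, 2] and bn.adjacency[0, 3]
        assert not bn.adjacency[1, 2]

    def test_idempotent_on_binary_input(self):
        rng = np.random.default_rng(3)
        a = (rng.random((8, 8)) < 0.4).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        m = int(a.sum() // 2)
        density = m / (8 * 7 / 2)
        bn = nmx.binarize_to_density(_fc(a + np.eye(8)), density)
        np.testing.assert_array_equal(bn.adjacency, a.astype(int))

    def test_tie_break_is_lexicographic(self):
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 1.0)
        bn = nmx.binarize_to_density(_fc(v), 0.5)
        again = nmx.binarize_to_density(_fc(v), 0.5)
        np.testing.assert_array_equal(bn.adjacency, again.adjacency)
        # first K upper-triangle pairs in (i, j) order: (0,1), (0,2), (0,3)
        assert bn.adjacency[0, 1] and bn.adjacency[0, 2] and bn.adjacency[0, 3]

    def test_density_within_one_edge(self):
        rng = np.random.default_rng(5)
        v = rng.random((10, 10))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        for dens in (0.2, 0.5, 0.8):
            bn = nmx.binarize_to_density(_fc(v), dens)
            assert abs(bn.m - dens * 45) <= 1

    def test_degenerate_densities_rejected(self):
        v = np.eye(4)
        with pytest.raises(ValueError):
            nmx.binarize_to_density(_fc(v), 0.01)
        with pytest.raises(ValueError):
            nmx.binarize_to_density(_fc(v), 0.999)


class TestPathLength:
    def test_complete_graph(self):
        a = 1 - np.eye(5, dtype=int)
        L, D, frac = nmx.average_path_length(nmx.BinaryNetwork(a))
        assert L == 1.0 and frac == 0.0

    def test_four_cycle(self):
        a = np.zeros((4, 4), dtype=int)
        for i in range(4):
            a[i, (i + 1) % 4] = a[(i + 1) % 4, i] = 1
        L, _, _ = nmx.average_path_length(nmx.BinaryNetwork(a))
        assert L == pytest.approx(4 / 3)

    def test_two_disjoint_triangles(self):
        a = np.zeros((6, 6), dtype=int)
        for block in (range(3), range(3, 6)):
            for i, j in itertools.combinations(block, 2):
                a[i, j] = a[j, i] = 1
        L, _, frac = nmx.average_path_length(nmx.BinaryNetwork(a))
        assert L == 1.0
        assert frac == pytest.approx(0.6)  # 18 of 30 ordered pairs disconnected

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            nmx.average_path_length(nmx.BinaryNetwork(np.zeros((3, 3), dtype=int)))


class TestClustering:
    def test_triangle_and_star(self):
        tri = 1 - np.eye(3, dtype=int)
        assert nmx.clustering_coefficient(nmx.BinaryNetwork(tri)) == 1.0
        star = np.zeros((5, 5), dtype=int)
        star[0, 1:] = star[1:, 0] = 1
        assert nmx.clustering_coefficient(nmx.BinaryNetwork(star)) == 0.0

    def test_four_cycle_with_diagonal(self):
        a = np.zeros((4, 4), dtype=int)
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)]:
            a[i, j] = a[j, i] = 1
        assert nmx.clustering_coefficient(nmx.BinaryNetwork(a)) == pytest.approx(
            clustering_oracle(a)
        )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    n=st.integers(4, 7),
    seed=st.integers(0, 10_000),
    p=st.floats(0.25, 0.9),
)
def test_metrics_match_exhaustive_oracles(n, seed, p):
    """L and C agree with Floyd-Warshall / triangle enumeration on small graphs."""
    rng = np.random.default_rng(seed)
    a = np.triu((rng.random((n, n)) < p).astype(int), 1)
    a = a + a.T
    if a.sum() == 0:
        return
    net = nmx.BinaryNetwork(a)
    L, D, frac = nmx.average_path_length(net)
    Do = fw_oracle(a)
    np.testing.assert_array_equal(D, Do)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(Do) & off
    assert L == pytest.approx(Do[finite].mean())
    assert nmx.clustering_coefficient(net) == pytest.approx(clustering_oracle(a), abs=1e-12)


class TestRandomReference:
    def test_complete_graph_reference(self):
        L, C = nmx.random_reference(5, 10, n_samples=10, seed=0)
        assert L == 1.0 and C == 1.0

    def test_er_clustering_near_density(self):
        n, p = 40, 0.3
        m = int(p * n * (n - 1) / 2)
        _, C = nmx.random_reference(n, m, n_samples=60, seed=1)
        se = np.sqrt(p * (1 - p) / (n * 3))
        assert abs(C - p) < 3 * max(se, 0.02)

    def test_seeded_reproducibility(self):
        assert nmx.random_reference(12, 20, seed=9) == nmx.random_reference(12, 20, seed=9)

    def test_m_out_of_range(self):
        with pytest.raises(ValueError):
            nmx.random_reference(5, 11)


class TestSmallWorld:
    def test_er_self_reference_near_one(self):
        import networkx as nx

        g = nx.gnm_random_graph(30, 90, seed=4)
        a = nx.to_numpy_array(g, dtype=int)
        met = nmx.characterize(nmx.BinaryNetwork(a), n_samples=100, seed=0)
        assert met.sw_index == pytest.approx(1.0, abs=0.35)

    def test_ring_lattice_with_shortcuts_is_small_world(self):
        import networkx as nx

        g = nx.connected_watts_strogatz_graph(60, 6, 0.05, seed=2)
        a = nx.to_numpy_array(g, dtype=int)
        met = nmx.characterize(nmx.BinaryNetwork(a), n_samples=30, seed=0)
        assert met.sw_index > 2.0

    def test_complete_graph_all_ones(self):
        a = 1 - np.eye(6, dtype=int)
        met = nmx.characterize(nmx.BinaryNetwork(a), n_samples=10, seed=0)
        assert met.lam == met.gamma == met.sw_index == 1.0


class TestJaccard:
    def test_identity_and_disjoint(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = 1
        b = np.zeros((4, 4), dtype=int)
        b[2, 3] = b[3, 2] = 1
        assert nmx.jaccard_similarity(a, a) == 1.0
        assert nmx.jaccard_similarity(a, b) == 0.0

    def test_half_overlap_example(self):
        a = np.zeros((3, 3), dtype=int)
        a[0, 1] = a[1, 0] = a[0, 2] = 1  # links (0,1),(1,0),(0,2)
        b = np.zeros((3, 3), dtype=int)
        b[0, 1] = b[1, 0] = b[1, 2] = 1  # links (0,1),(1,0),(1,2)
        assert nmx.jaccard_similarity(a, b) == 0.5

    def test_symmetry_and_size_mismatch(self):
        rng = np.random.default_rng(0)
        a = (rng.random((5, 5)) < 0.5).astype(int)
        b = (rng.random((5, 5)) < 0.5).astype(int)
        np.fill_diagonal(a, 0)
        np.fill_diagonal(b, 0)
        assert nmx.jaccard_similarity(a, b) == nmx.jaccard_similarity(b, a)
        with pytest.raises(ValueError):
            nmx.jaccard_similarity(a, np.zeros((4, 4), dtype=int))

    def test_empty_union_is_nan(self):
        z = np.zeros((3, 3), dtype=int)
        assert np.isnan(nmx.jaccard_similarity(z, z))

    def test_degrades_under_rewiring(self):
        """Expected agreement with the original drops as edges are moved away."""
        rng = np.random.default_rng(7)
        n = 12
        a = np.triu((rng.random((n, n)) < 0.4).astype(int), 1)
        a = a + a.T
        iu, ju = np.triu_indices(n, 1)
        on = np.flatnonzero(a[iu, ju])
        off = np.flatnonzero(a[iu, ju] == 0)
        means = []
        for n_moved in (0, 3, 8):
            vals = []
            for _ in range(30):
                b = a.copy()
                src = rng.choice(on, size=n_moved, replace=False)
                dst = rng.choice(off, size=n_moved, replace=False)
                b[iu[src], ju[src]] = b[ju[src], iu[src]] = 0
                b[iu[dst], ju[dst]] = b[ju[dst], iu[dst]] = 1
                vals.append(nmx.jaccard_similarity(a, b))
            means.append(np.mean(vals))
        assert means[0] == 1.0
        assert means[0] > means[1] > means[2]

    def test_chance_level_matches_hypergeometric_expectation(self):
        a = np.zeros((12, 12), dtype=int)
        iu, ju = np.triu_indices(12, 1)
        a[iu[:18], ju[:18]] = 1
        a = a + a.T
        mean, sd = nmx.jaccard_chance_level(nmx.BinaryNetwork(a), 18, n_permutations=300, seed=0)
        # E[intersection] = 18*18/66 ~ 4.91 -> J ~ 0.16
        assert mean == pytest.approx(0.16, abs=0.03)
        assert 0 < sd < 0.12
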