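"""Graph-theoretic characterization of binarized FC and SC-FC agreement.

The functional-connectivity matrix is binarized at matched density: the
threshold is chosen so the resulting undirected graph has the same number of
links as the (OR-symmetrized) structural matrix.  The binary graph is then
summarized by the average shortest-path length L, the global clustering
coefficient C, their Erdos-Renyi ensemble references L_rand and C_rand, the
relative coefficients lambda = L/L_rand and gamma = C/C_rand, and the
small-world index gamma/lambda.  Agreement between binary SC and FC link
sets is the Jaccard similarity coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectome import StructuralConnectivity
from .fc_measures import FCMatrix

__all__ = [
    "BinaryNetwork",
    "NetworkMetrics",
    "binarize_to_density",
    "average_path_length",
    "clustering_coefficient",
    "random_reference",
    "small_world_index",
    "jaccard_similarity",
    "jaccard_chance_level",
    "characterize",
]


@dataclass
class BinaryNetwork:
    """Undirected binary graph as a symmetric adjacency with zero diagonal."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric (undirected graph)")
        if np.any(np.diag(a) != 0):
            raise ValueError("diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = a.astype(np.int8)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def m(self) -> int:
        """Number of undirected edges."""
        return int(self.adjacency.sum()) // 2

    def to_networkx(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency)


@dataclass
class NetworkMetrics:
    """L, C, random-graph references and derived small-world quantities."""

    L: float
    C: float
    L_rand: float
    C_rand: float
    lam: float
    gamma: float
    sw_index: float
    disconnected_pair_fraction: float


def _as_binary(net) -> BinaryNetwork:
    if isinstance(net, BinaryNetwork):
        return net
    if isinstance(net, StructuralConnectivity):
        return BinaryNetwork(net.undirected())
    return BinaryNetwork(np.asarray(net))


def binarize_to_density(fc: FCMatrix, target_density: float) -> BinaryNetwork:
    """Keep the K strongest off-diagonal links, K = round(density * n(n-1)/2).

    Ties are broken by (i, j) lexicographic order of the upper-triangle
    entries, so the result is deterministic.
    """
    if not 0 < target_density < 1:
        raise ValueError("target_density must be in (0, 1)")
    v = fc.values
    n = v.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    n_pairs = len(iu)
    k = int(round(target_density * n_pairs))
    if k == 0 or k == n_pairs:
        raise ValueError(
            f"target_density {target_density} keeps {k} of {n_pairs} links; "
            "must keep at least one and not all"
        )
    vals = v[iu, ju]
    # stable sort on descending value; equal values stay in (i, j) lex order
    order = np.argsort(-vals, kind="stable")[:k]
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[order], ju[order]] = 1
    return BinaryNetwork(a + a.T)


def average_path_length(net) -> tuple[float, np.ndarray, float]:
    """(L, distance matrix, disconnected pair fraction).

    Distances are BFS hop counts; L averages over *connected* ordered pairs
    only, and the fraction of disconnected ordered pairs is reported
    alongside.  Disconnected entries of the distance matrix are ``inf``.
    """
    net = _as_binary(net)
    if net.n < 2:
        raise ValueError("need at least 2 nodes")
    if net.m == 0:
        raise ValueError("edgeless graph has no path lengths")
    g = net.to_networkx()
    n = net.n
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for src, dists in nx.all_pairs_shortest_path_length(g):
        for dst, d in dists.items():
            D[src, dst] = d
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    n_pairs = n * (n - 1)
    frac_disc = 1.0 - finite.sum() / n_pairs
    L = float(D[finite].mean())
    return L, D, float(frac_disc)


def clustering_coefficient(net) -> float:
    """Global clustering coefficient: mean local clustering over all nodes.

    A node's local coefficient is the fraction of realized links among its
    neighbours; nodes with degree < 2 contribute 0.
    """
    net = _as_binary(net)
    if net.n < 3:
        raise ValueError("need at least 3 nodes")
    return float(nx.average_clustering(net.to_networkx(), count_zeros=True))


def random_reference(
    n: int, m: int, n_samples: int = 100, seed: int | None = None
) -> tuple[float, float]:
    """Ensemble means (L_rand, C_rand) over seeded G(n, m) random graphs.

    Uses the same connected-pairs convention for L as
    :func:`average_path_length`.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    max_m = n * (n - 1) // 2
    if not 1 <= m <= max_m:
        raise ValueError(f"m must be in [1, {max_m}]")
    rng = np.random.default_rng(seed)
    Ls, Cs = [], []
    for _ in range(n_samples):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        a = nx.to_numpy_array(g, dtype=np.int8)
        net = BinaryNetwork(a)
        L, _, _ = average_path_length(net)
        Ls.append(L)
        Cs.append(clustering_coefficient(net))
    return float(np.mean(Ls)), float(np.mean(Cs))


def small_world_index(net, reference: tuple[float, float]) -> NetworkMetrics:
    """Populate lambda = L/L_rand, gamma = C/C_rand and sw = gamma/lambda.

    ``reference`` is (L_rand, C_rand) from :func:`random_reference` with
    matching n and m.  A zero reference clustering makes gamma and the
    small-world index undefined (NaN).
    """
    net = _as_binary(net)
    L, _, frac_disc = average_path_length(net)
    C = clustering_coefficient(net)
    L_rand, C_rand = reference
    lam = L / L_rand if L_rand > 0 else np.nan
    gamma = C / C_rand if C_rand > 0 else np.nan
    sw = gamma / lam if np.isfinite(gamma) and np.isfinite(lam) and lam > 0 else np.nan
    return NetworkMetrics(
        L=L,
        C=C,
        L_rand=L_rand,
        C_rand=C_rand,
        lam=lam,
        gamma=gamma,
        sw_index=sw,
        disconnected_pair_fraction=frac_disc,
    )


def characterize(net, n_samples: int = 100, seed: int | None = None) -> NetworkMetrics:
    """Convenience: metrics of ``net`` against its own G(n, m) ensemble."""
    net = _as_binary(net)
    ref = random_reference(net.n, net.m, n_samples=n_samples, seed=seed)
    return small_world_index(net, ref)


def jaccard_similarity(a, b) -> float:
    """Shared links / union of links, over off-diagonal entries.

    Accepts :class:`BinaryNetwork`, :class:`StructuralConnectivity` (its
    binary adjacency is used as-is if directed symmetry is wanted, use
    ``.undirected()`` upstream) or a raw binary matrix.  Returns NaN (with
    no links anywhere, agreement is undefined).
    """
    am = a.adjacency if isinstance(a, BinaryNetwork) else (
        a.b if isinstance(a, StructuralConnectivity) else np.asarray(a)
    )
    bm = b.adjacency if isinstance(b, BinaryNetwork) else (
        b.b if isinstance(b, StructuralConnectivity) else np.asarray(b)
    )
    if am.shape != bm.shape:
        raise ValueError(f"size mismatch: {am.shape} vs {bm.shape}")
    if not (np.isin(am, (0, 1)).all() and np.isin(bm, (0, 1)).all()):
        raise ValueError("inputs must be binary")
    off = ~np.eye(am.shape[0], dtype=bool)
    inter = int(np.sum((am == 1) & (bm == 1) & off))
    union = int(np.sum(((am == 1) | (bm == 1)) & off))
    if union == 0:
        return float("nan")
    return inter / union


def jaccard_chance_level(
    reference, m_edges: int, n_permutations: int = 100, seed: int | None = None
) -> tuple[float, float]:
    """Chance level of the Jaccard agreement for an edge-permuted FC graph.

    Places ``m_edges`` undirected links uniformly at random and computes the
    Jaccard similarity against ``reference``; returns (mean, standard
    deviation) over ``n_permutations`` seeded draws.  This quantifies the
    "no structure" baseline against which a measured agreement is judged.
    """
    ref = _as_binary(reference)
    rng = np.random.default_rng(seed)
    n = ref.n
    iu, ju = np.triu_indices(n, k=1)
    vals = []
    for _ in range(n_permutations):
        pick = rng.choice(len(iu), size=m_edges, replace=False)
        a = np.zeros((n, n), dtype=np.int8)
        a[iu[pick], ju[pick]] = 1
        vals.append(jaccard_similarity(BinaryNetwork(a + a.T), ref))
    return float(np.mean(vals)), float(np.std(vals, ddof=1))
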