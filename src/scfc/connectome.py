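"""Structural connectivity: generation, randomization, normalization and I/O.

Structural connectivity (SC) is a binary directed adjacency matrix ``b`` with
the convention ``b[i, j] = 1`` meaning an anatomical link from node ``j`` to
node ``i`` (column = source).  The simulator consumes row-normalized weights
``w[i, j] = b[i, j] / in_degree(i)`` so that the total input to each node is
normalised.  Three families of matrices are provided: purely modular
networks (fully connected blocks, nothing between them), a seeded synthetic
"cortex-like" fixture emulating the size and modular tendency of macaque
cortical parcellations, and degree-preserving randomizations of any matrix
by Maslov-Sneppen edge swaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StructuralConnectivity",
    "modular_sc",
    "rewire_degree_preserving",
    "normalize_rows",
    "synthetic_cortex_fixture",
    "read_adjacency",
    "write_adjacency",
]

logger = logging.getLogger(__name__)


@dataclass
class StructuralConnectivity:
    """Binary adjacency ``b`` plus row-normalized weights ``w``.

    Invariants: zero diagonal; ``w[i, j] > 0`` iff ``b[i, j] == 1``; every
    row of ``w`` with positive in-degree sums to exactly 1.
    """

    n: int
    b: np.ndarray
    w: np.ndarray
    directed: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b)
        self.w = np.asarray(self.w, dtype=float)
        if self.b.shape != (self.n, self.n) or self.w.shape != (self.n, self.n):
            raise ValueError("b and w must be n x n")
        if np.any(np.diag(self.b) != 0) or np.any(np.diag(self.w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any((self.w > 0) != (self.b == 1)):
            raise ValueError("support of w must equal support of b")

    @property
    def n_edges(self) -> int:
        """Number of directed links."""
        return int(self.b.sum())

    @property
    def density(self) -> float:
        """Directed density, edges / (n*(n-1))."""
        return self.n_edges / (self.n * (self.n - 1))

    def undirected(self) -> np.ndarray:
        """OR-symmetrized binary adjacency (link if either direction exists)."""
        return ((self.b + self.b.T) > 0).astype(np.int8)


def normalize_rows(b: np.ndarray, label: str = "", directed: bool = True) -> StructuralConnectivity:
    """Build a :class:`StructuralConnectivity` from a binary adjacency matrix.

    ``w[i, j] = b[i, j] / sum_k b[i, k]``; all-zero rows (nodes with no
    afferents) are left all-zero and logged.
    """
    b = np.asarray(b)
    if b.ndim != 2 or b.shape[0] != b.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {b.shape}")
    if not np.isin(b, (0, 1)).all():
        raise ValueError("adjacency must be binary (entries 0 or 1)")
    diag = np.flatnonzero(np.diag(b))
    if diag.size:
        raise ValueError(f"nonzero diagonal entry at node {diag[0]}")
    b = b.astype(np.int8)
    indeg = b.sum(axis=1)
    empty = np.flatnonzero(indeg == 0)
    if empty.size:
        logger.warning("nodes %s have in-degree 0; their weight rows stay zero", empty.tolist())
    w = b.astype(float)
    nz = indeg > 0
    w[nz] /= indeg[nz, None]
    return StructuralConnectivity(n=b.shape[0], b=b, w=w, directed=directed, label=label)


def modular_sc(n_modules: int, module_size: int) -> StructuralConnectivity:
    """Purely modular SC: blocks fully connected inside, nothing between.

    Each of the ``n_modules`` blocks of ``module_size`` nodes is an
    all-to-all directed graph without self-loops.
    """
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    if module_size < 2:
        raise ValueError("module_size must be >= 2 (size-1 modules have isolated nodes)")
    n = n_modules * module_size
    b = np.zeros((n, n), dtype=np.int8)
    for m in range(n_modules):
        s = slice(m * module_size, (m + 1) * module_size)
        b[s, s] = 1
    np.fill_diagonal(b, 0)
    return normalize_rows(b, label=f"modular-{n_modules}x{module_size}")


def rewire_degree_preserving(
    sc: StructuralConnectivity, swaps_per_edge: int = 10, seed: int | None = None
) -> StructuralConnectivity:
    """Maslov-Sneppen randomization preserving in- and out-degree sequences.

    Repeatedly picks two directed edges ``a->b``, ``c->d`` and swaps their
    targets to ``a->d``, ``c->b``; a swap is rejected if it would create a
    self-loop or a duplicate edge.  The attempt budget is
    ``swaps_per_edge * n_edges``.  If no swap ever succeeds (pathological
    graphs) the input is returned unchanged with a warning.
    """
    rng = np.random.default_rng(seed)
    b = sc.b.copy()
    # edge list as (target i, source j): b[i, j] = 1 means j -> i
    targets, sources = np.nonzero(b)
    m = len(sources)
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    n_accepted = 0
    for _ in range(swaps_per_edge * m):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, bb = sources[e1], targets[e1]
        c, d = sources[e2], targets[e2]
        # proposed: a->d and c->b
        if a == d or c == bb:
            continue
        if b[d, a] or b[bb, c]:
            continue
        b[bb, a] = 0
        b[d, c] = 0
        b[d, a] = 1
        b[bb, c] = 1
        targets[e1] = d
        targets[e2] = bb
        n_accepted += 1
    if n_accepted == 0:
        logger.warning("no legal edge swap found within budget; returning input unchanged")
        return normalize_rows(sc.b.copy(), label=sc.label + "+rewired(noop)")
    return normalize_rows(b, label=sc.label + "+rewired")


def synthetic_cortex_fixture(n: int = 47, seed: int | None = 0) -> StructuralConnectivity:
    """Seeded synthetic stand-in for a macaque-cortex-scale connectome.

    This is a synthetic fixture, not anatomical data: a directed
    stochastic-block-model graph with a planted modular tendency (5
    communities by default-size split, within-community link probability far
    above between), tuned so the directed density lands in [0.1, 0.3] and
    the OR-symmetrized graph is connected.  It emulates only the size,
    density and modularity of tract-tracing matrices such as CoComac.
    """
    if n < 8:
        raise ValueError("n must be >= 8")
    rng = np.random.default_rng(seed)
    n_comm = 5 if n >= 20 else 4
    # balanced community sizes
    sizes = np.full(n_comm, n // n_comm)
    sizes[: n % n_comm] += 1
    comm = np.repeat(np.arange(n_comm), sizes)
    p_in, p_out = 0.65, 0.06
    for attempt in range(100):
        same = comm[:, None] == comm[None, :]
        prob = np.where(same, p_in, p_out)
        b = (rng.random((n, n)) < prob).astype(np.int8)
        np.fill_diagonal(b, 0)
        sc = normalize_rows(b, label=f"synthetic-cortex-n{n}")
        if 0.1 <= sc.density <= 0.3 and _connected_undirected(b):
            return sc
    raise RuntimeError("could not generate a connected fixture in the density band")


def _connected_undirected(b: np.ndarray) -> bool:
    """Breadth-first-search connectivity of the OR-symmetrized graph."""
    n = b.shape[0]
    adj = (b + b.T) > 0
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(adj[i] & ~seen):
            seen[j] = True
            stack.append(int(j))
    return bool(seen.all())


def write_adjacency(sc: StructuralConnectivity, path, fmt: str = "dense") -> None:
    """Write the binary adjacency as dense CSV or as a 0-based edge list.

    Edge-list lines are ``source target`` (one directed edge per line) under
    a ``# source target`` header; dense files are comma-separated 0/1 rows.
    """
    if fmt == "dense":
        np.savetxt(path, sc.b, fmt="%d", delimiter=",")
    elif fmt == "edgelist":
        targets, sources = np.nonzero(sc.b)
        with open(path, "w") as fh:
            fh.write(f"# source target (0-based, n={sc.n})\n")
            for s, t in zip(sources, targets):
                fh.write(f"{s} {t}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_adjacency(path, n: int | None = None, label: str | None = None) -> StructuralConnectivity:
    """Read a dense numeric text matrix or a two-column edge list.

    Dense: square comma/whitespace separated 0/1 matrix, zero diagonal.
    Edge list: ``source target`` 0-based indices, one directed edge per
    line; ``n`` may be given or is inferred from a header comment or the
    largest index.  Parse failures report the offending line.
    """
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = [
        (k + 1, ln.strip()) for k, ln in enumerate(lines) if ln.strip() and not ln.strip().startswith("#")
    ]
    if not data_lines:
        raise ValueError(f"{path}: no data lines")
    n_cols = len(data_lines[0][1].replace(",", " ").split())
    is_edgelist = n_cols == 2 and len(data_lines) != 2

    header_n = None
    for ln in lines:
        if ln.startswith("#") and "n=" in ln:
            header_n = int(ln.split("n=")[1].rstrip(")\n "))

    if n_cols == 2 and len(data_lines) == 2:
        # ambiguous 2x2: dense if every entry is 0/1 and diagonal zero
        try:
            mat = _parse_dense(data_lines, path)
            return normalize_rows(mat, label=label or str(path))
        except ValueError:
            is_edgelist = True

    if is_edgelist:
        edges = []
        for lineno, ln in data_lines:
            parts = ln.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'source target', got {ln!r}")
            try:
                s, t = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer node index in {ln!r}") from exc
            edges.append((lineno, s, t))
        size = n or header_n or (max(max(s, t) for _, s, t in edges) + 1)
        b = np.zeros((size, size), dtype=np.int8)
        for lineno, s, t in edges:
            if not (0 <= s < size and 0 <= t < size):
                raise ValueError(f"{path}:{lineno}: node index out of range [0, {size})")
            if s == t:
                raise ValueError(f"{path}:{lineno}: self-loop {s}->{t} not allowed")
            b[t, s] = 1
        return normalize_rows(b, label=label or str(path))

    mat = _parse_dense(data_lines, path)
    return normalize_rows(mat, label=label or str(path))


def _parse_dense(data_lines, path) -> np.ndarray:
    rows = []
    for lineno, ln in data_lines:
        try:
            rows.append([float(x) for x in ln.replace(",", " ").split()])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric entry") from exc
    mat = np.array(rows)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: dense matrix is not square: shape {mat.shape}")
    if not np.isin(mat, (0.0, 1.0)).all():
        raise ValueError(f"{path}: dense adjacency entries must be 0 or 1")
    bad = np.flatnonzero(np.diag(mat))
    if bad.size:
        raise ValueError(f"{path}: nonzero diagonal entry at row {bad[0]} (node {bad[0]})")
    return mat.astype(np.int8)
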