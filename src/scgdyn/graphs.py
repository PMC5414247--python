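"""Strongly connected directed graphs: construction, validation, randomisation.

A strongly connected graph (SCG) is a directed graph in which every vertex
reaches every other vertex along directed edges; equivalently, its adjacency
matrix is irreducible.  Random n-vertex SCGs with every in- and out-degree
exactly ``z`` are sampled by a degree-preserving edge-swap Markov chain:

1. seed with the union of ``z`` edge-disjoint random Hamiltonian directed
   cycles (z-regular and strongly connected by construction — "contrived"
   in the sense of being long and thin);
2. apply double-edge swaps ``(a,b),(c,d) -> (a,d),(c,b)``, rejecting any
   proposal that duplicates an edge, creates a self-loop, or disconnects
   the graph.  Swaps preserve every vertex's in- and out-degree, so the
   chain random-walks inside the set of z-regular SCGs, and the diameter
   tends to shrink towards that of a typical random regular digraph.

Transmission lags are drawn i.i.d. Uniform(low, high) per edge, from an RNG
stream independent of the topology stream, so the same seed yields the same
graph whether or not lags are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .errors import GenerationError, GraphError, ParameterError

__all__ = [
    "DirectedGraph",
    "GenParams",
    "LagMap",
    "is_strongly_connected",
    "irreducibility_oracle",
    "seed_graph",
    "edge_swap_step",
    "swap_chain",
    "generate_scg",
    "generate_scg_with_lags",
    "graph_diameter",
    "assign_lags",
    "write_graph_tsv",
    "read_graph_tsv",
]

_SEED_CYCLE_RETRIES = 200
_SWAP_PICK_RETRIES = 100


@dataclass(frozen=True)
class DirectedGraph:
    """Simple directed graph: ``n`` vertices (0-based), no self-loops,
    at most one edge per ordered pair."""

    n: int
    edges: frozenset

    def __post_init__(self) -> None:
        if self.n < 1:
            raise GraphError("graph must have at least one vertex")
        edges = frozenset((int(i), int(j)) for i, j in self.edges)
        object.__setattr__(self, "edges", edges)
        for i, j in edges:
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise GraphError(f"vertex index out of range in edge ({i}, {j})")
            if i == j:
                raise GraphError(f"self-loop at vertex {i}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def out_adjacency(self) -> list:
        adj = [[] for _ in range(self.n)]
        for i, j in self.edges:
            adj[i].append(j)
        return adj

    def in_adjacency(self) -> list:
        adj = [[] for _ in range(self.n)]
        for i, j in self.edges:
            adj[j].append(i)
        return adj

    def out_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for i, _ in self.edges:
            deg[i] += 1
        return deg

    def in_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for _, j in self.edges:
            deg[j] += 1
        return deg

    def adjacency_matrix(self) -> np.ndarray:
        A = np.zeros((self.n, self.n), dtype=np.int64)
        for i, j in self.edges:
            A[i, j] = 1
        return A


@dataclass(frozen=True)
class GenParams:
    """Parameters of the SCG sampler.

    n        vertex count
    z        exact in/out degree of every vertex (1 <= z <= n-1)
    n_swaps  number of edge-swap *attempts* (rejections count)
    seed     master seed; topology and lags use independent child streams
    """

    n: int
    z: int
    n_swaps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError("need n >= 2")
        if not (1 <= self.z <= self.n - 1):
            raise ParameterError(
                f"need 1 <= z <= n-1 (got z={self.z}, n={self.n})"
            )
        if self.n_swaps < 0:
            raise ParameterError("n_swaps must be non-negative")


@dataclass(frozen=True)
class LagMap:
    """Positive transmission delay per directed edge, plus the draw bounds."""

    lags: Mapping
    low: float
    high: float

    def __getitem__(self, edge) -> float:
        return self.lags[edge]

    def __len__(self) -> int:
        return len(self.lags)

    def __contains__(self, edge) -> bool:
        return edge in self.lags


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------


def _reaches_all(n: int, adj: list, start: int = 0) -> bool:
    seen = bytearray(n)
    seen[start] = 1
    count = 1
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if not seen[v]:
                seen[v] = 1
                count += 1
                stack.append(v)
    return count == n


def is_strongly_connected(g: DirectedGraph) -> bool:
    """Two depth-first searches: vertex 0 must reach every vertex in the
    graph and in the edge-reversed graph."""
    if g.n == 1:
        return True
    return _reaches_all(g.n, g.out_adjacency()) and _reaches_all(
        g.n, g.in_adjacency()
    )


def irreducibility_oracle(g: DirectedGraph) -> bool:
    """Matrix-power irreducibility criterion.

    A is irreducible iff every off-diagonal entry of ``sum_{k=1}^{n-1} A^k``
    is strictly positive (a directed path between distinct vertices, if one
    exists, has length at most n-1; each vertex reaches itself trivially,
    so the diagonal carries no information — e.g. a pure 3-cycle has a zero
    diagonal at powers 1..2).  Equivalent to ``(I + A)^{n-1} > 0``.  O(n^4);
    intended as an independent cross-check for small n.
    """
    n = g.n
    if n == 1:
        return True
    A = g.adjacency_matrix()
    P = np.eye(n, dtype=np.int64)
    S = np.zeros((n, n), dtype=np.int64)
    for _ in range(n - 1):
        P = np.minimum(P @ A, 1)  # boolean power; clip to avoid overflow
        S += P
    off_diag = ~np.eye(n, dtype=bool)
    return bool((S[off_diag] > 0).all())


# ---------------------------------------------------------------------------
# Seed construction and the edge-swap chain
# ---------------------------------------------------------------------------


def seed_graph(params: GenParams, rng: np.random.Generator) -> DirectedGraph:
    """Contrived z-regular seed: z edge-disjoint Hamiltonian directed cycles.

    A single random cyclic order ``perm`` is traversed with stride s for
    each of the first z strides coprime to n: every stride-s cycle is
    Hamiltonian (gcd(s, n) = 1), distinct strides are edge-disjoint, and
    the union is exactly z-regular and strongly connected.  This permuted
    circulant is deliberately "long and thin" (diameter of order n/z), the
    contrived end of the space from which the swap chain relaxes towards
    homogeneous random regular digraphs with much smaller diameter.  If n
    has fewer than z coprime strides, the remaining cycles are drawn as
    independent random Hamiltonian cycles with disjointness retries.
    """
    n, z = params.n, params.z
    perm = rng.permutation(n)
    strides = [s for s in range(1, n) if np.gcd(s, n) == 1][:z]
    edges = set()
    for s in strides:
        edges.update(
            (int(perm[t]), int(perm[(t + s) % n])) for t in range(n)
        )
    for _ in range(z - len(strides)):
        for _attempt in range(_SEED_CYCLE_RETRIES):
            extra = rng.permutation(n)
            cycle = [
                (int(extra[t]), int(extra[(t + 1) % n])) for t in range(n)
            ]
            if edges.isdisjoint(cycle):
                edges.update(cycle)
                break
        else:
            raise GenerationError(
                f"could not find {z} edge-disjoint Hamiltonian cycles "
                f"on {n} vertices within {_SEED_CYCLE_RETRIES} retries"
            )
    return DirectedGraph(n, frozenset(edges))


class _ChainState:
    """Mutable edge-swap chain state: edge list for uniform picks, edge set
    for O(1) membership, adjacency sets for connectivity checks."""

    __slots__ = ("n", "edge_list", "edge_set", "out_adj", "in_adj")

    def __init__(self, g: DirectedGraph) -> None:
        self.n = g.n
        self.edge_list = sorted(g.edges)
        self.edge_set = set(self.edge_list)
        self.out_adj = [set() for _ in range(g.n)]
        self.in_adj = [set() for _ in range(g.n)]
        for i, j in self.edge_list:
            self.out_adj[i].add(j)
            self.in_adj[j].add(i)

    def _connected(self) -> bool:
        return _reaches_all(self.n, self.out_adj) and _reaches_all(
            self.n, self.in_adj
        )

    def attempt_swap(self, rng: np.random.Generator) -> bool:
        """One proposal of the chain; returns True iff it was accepted."""
        m = len(self.edge_list)
        if m < 2:
            return False
        for _ in range(_SWAP_PICK_RETRIES):
            i = int(rng.integers(m))
            j = int(rng.integers(m))
            if i == j:
                continue
            a, b = self.edge_list[i]
            c, d = self.edge_list[j]
            if a == c or b == d or a == d or c == b:
                continue
            break
        else:
            return False
        if (a, d) in self.edge_set or (c, b) in self.edge_set:
            return False
        # apply tentatively, then verify strong connectivity
        self.edge_set.discard((a, b))
        self.edge_set.discard((c, d))
        self.edge_set.add((a, d))
        self.edge_set.add((c, b))
        self.out_adj[a].discard(b)
        self.out_adj[c].discard(d)
        self.out_adj[a].add(d)
        self.out_adj[c].add(b)
        self.in_adj[b].discard(a)
        self.in_adj[d].discard(c)
        self.in_adj[d].add(a)
        self.in_adj[b].add(c)
        if self._connected():
            self.edge_list[i] = (a, d)
            self.edge_list[j] = (c, b)
            return True
        # revert
        self.edge_set.discard((a, d))
        self.edge_set.discard((c, b))
        self.edge_set.add((a, b))
        self.edge_set.add((c, d))
        self.out_adj[a].discard(d)
        self.out_adj[c].discard(b)
        self.out_adj[a].add(b)
        self.out_adj[c].add(d)
        self.in_adj[d].discard(a)
        self.in_adj[b].discard(c)
        self.in_adj[b].add(a)
        self.in_adj[d].add(c)
        return False

    def graph(self) -> DirectedGraph:
        return DirectedGraph(self.n, frozenset(self.edge_set))


def edge_swap_step(
    g: DirectedGraph, rng: np.random.Generator
) -> DirectedGraph:
    """One degree-preserving double-edge swap attempt.

    Picks two edges (a,b), (c,d) uniformly with a≠c, b≠d, a≠d, c≠b and
    proposes (a,d), (c,b).  The proposal is rejected (``g`` returned
    unchanged) if either new edge already exists or the swapped graph is no
    longer strongly connected.
    """
    if not is_strongly_connected(g):
        raise GraphError("edge_swap_step requires a strongly connected graph")
    state = _ChainState(g)
    if state.attempt_swap(rng):
        return state.graph()
    return g


def swap_chain(
    g: DirectedGraph, n_swaps: int, rng: np.random.Generator
) -> Iterator[DirectedGraph]:
    """Yield the graph after each of ``n_swaps`` swap attempts (rejected
    attempts yield the unchanged graph)."""
    state = _ChainState(g)
    for _ in range(n_swaps):
        state.attempt_swap(rng)
        yield state.graph()


def _topology_lag_streams(seed: int):
    topo_ss, lag_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(topo_ss), np.random.default_rng(lag_ss)


def generate_scg(params: GenParams) -> DirectedGraph:
    """Seed graph followed by ``params.n_swaps`` swap attempts.

    Deterministic given ``params.seed``; the topology stream is independent
    of the lag stream used by :func:`generate_scg_with_lags`.
    """
    rng, _ = _topology_lag_streams(params.seed)
    state = _ChainState(seed_graph(params, rng))
    for _ in range(params.n_swaps):
        state.attempt_swap(rng)
    return state.graph()


def generate_scg_with_lags(
    params: GenParams, low: float, high: float
):
    """Convenience: sampled SCG plus i.i.d. Uniform(low, high) edge lags,
    both reproducible from ``params.seed`` alone."""
    g = generate_scg(params)
    _, lag_rng = _topology_lag_streams(params.seed)
    return g, assign_lags(g, low, high, lag_rng)


# ---------------------------------------------------------------------------
# Graph metrics and lags
# ---------------------------------------------------------------------------


def graph_diameter(g: DirectedGraph) -> int:
    """Maximum over ordered vertex pairs of the shortest directed path
    length (unweighted)."""
    if g.n == 1:
        return 0
    rows, cols = zip(*g.edges) if g.edges else ((), ())
    A = csr_matrix(
        (np.ones(len(g.edges)), (rows, cols)), shape=(g.n, g.n)
    )
    D = shortest_path(A, method="D", directed=True, unweighted=True)
    if np.isinf(D).any():
        raise GraphError("diameter undefined: graph is not strongly connected")
    return int(D.max())


def assign_lags(
    g: DirectedGraph, low: float, high: float, rng: np.random.Generator
) -> LagMap:
    """One independent Uniform(low, high) transmission delay per edge.

    ``low == high`` is the degenerate point mass.  Edges are enumerated in
    sorted order so the draw is reproducible for a given seed.
    """
    if low <= 0:
        raise ParameterError("lag lower bound must be positive")
    if high < low:
        raise ParameterError("lag upper bound must be >= lower bound")
    edges = sorted(g.edges)
    if low == high:
        draws = np.full(len(edges), float(low))
    else:
        draws = rng.uniform(low, high, size=len(edges))
    return LagMap(dict(zip(edges, map(float, draws))), float(low), float(high))


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------


def write_graph_tsv(path, g: DirectedGraph, lags: LagMap) -> None:
    """Write `src  dst  lag` TSV (0-based vertices, '#' comments)."""
    path = Path(path)
    edges = sorted(g.edges)
    frame = pd.DataFrame(
        {
            "src": [i for i, _ in edges],
            "dst": [j for _, j in edges],
            "lag": [lags[e] for e in edges],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# n: {g.n}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_graph_tsv(path):
    """Read a `src  dst  lag` TSV; returns (DirectedGraph, LagMap)."""
    path = Path(path)
    n_declared = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "n:" in line:
                n_declared = int(line.split("n:")[1].strip())
                break
    frame = pd.read_csv(
        path, sep="\t", comment="#", float_precision="round_trip"
    )
    edges = frozenset(
        (int(r.src), int(r.dst)) for r in frame.itertuples(index=False)
    )
    n = n_declared
    if n is None:
        n = int(max(max(i, j) for i, j in edges)) + 1
    g = DirectedGraph(n, edges)
    lag_values = [float(v) for v in frame["lag"]]
    lags = dict(
        zip(
            ((int(r.src), int(r.dst)) for r in frame.itertuples(index=False)),
            lag_values,
        )
    )
    if any(v <= 0 for v in lag_values):
        raise ParameterError("all lags must be positive")
    return g, LagMap(lags, min(lag_values), max(lag_values))
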