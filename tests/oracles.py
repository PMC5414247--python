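"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's algorithms: the spike-dynamics
oracle steps time tick by tick on a fixed 10^-3 grid instead of processing
a priority queue, and the graph oracles use dense matrix powers /
Floyd-Warshall instead of searches.
"""

from __future__ import annotations

import numpy as np

TICKS_PER_UNIT = 1000  # grid resolution 10^-3 time units


def grid_simulate(n, edges_with_lag_ticks, delta_ticks, kick_vertex,
                  horizon_ticks, forcing_period_ticks=None,
                  force_vertex=None):
    """Fine-grid time-stepping simulation in integer ticks.

    edges_with_lag_ticks: iterable of (src, dst, lag_ticks).
    Returns a list of (tick, vertex) spikes in processing order.
    Conventions mirror the declared ones: refractory window [t, t+delta);
    coincident arrivals handled in ascending vertex order.
    """
    out = [[] for _ in range(n)]
    for i, j, lag in edges_with_lag_ticks:
        out[i].append((int(lag), j))
    pending = {}  # tick -> set of target vertices

    def schedule(tick, target):
        pending.setdefault(tick, set()).add(target)

    if forcing_period_ticks is None:
        schedule(0, kick_vertex)
    else:
        t = 0
        while t <= horizon_ticks:
            schedule(t, force_vertex)
            t += forcing_period_ticks

    last = [None] * n
    spikes = []
    tick = 0
    while tick <= horizon_ticks:
        if tick in pending:
            for v in sorted(pending.pop(tick)):
                lv = last[v]
                if lv is None or tick - lv >= delta_ticks:
                    last[v] = tick
                    spikes.append((tick, v))
                    for lag, w in out[v]:
                        schedule(tick + lag, w)
        tick += 1
    return spikes


def floyd_warshall_diameter(n, edges):
    """All-pairs shortest directed path lengths by Floyd-Warshall; returns
    the maximum, or None if some pair is unreachable."""
    INF = float("inf")
    D = [[INF] * n for _ in range(n)]
    for i in range(n):
        D[i][i] = 0
    for i, j in edges:
        D[i][j] = 1
    for k in range(n):
        Dk = D[k]
        for i in range(n):
            Di = D[i]
            dik = Di[k]
            if dik == INF:
                continue
            for j in range(n):
                alt = dik + Dk[j]
                if alt < Di[j]:
                    Di[j] = alt
    worst = max(max(row) for row in D)
    return None if worst == INF else int(worst)


def reachability_strongly_connected(n, edges):
    """Strong connectivity by transitive closure of the boolean adjacency
    matrix (repeated squaring of I + A)."""
    R = np.eye(n, dtype=bool)
    A = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        A[i, j] = True
    R = R | A
    for _ in range(max(1, int(np.ceil(np.log2(max(n, 2)))))):
        R = R | (R @ R)
    return bool(R.all())


def random_digraph(n, edge_prob, rng):
    """Erdos-Renyi style random digraph edge set (no self-loops)."""
    edges = set()
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < edge_prob:
                edges.add((i, j))
    return edges
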