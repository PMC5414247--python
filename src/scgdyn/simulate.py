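"""Event-driven simulation of excitable-refractory spike dynamics.

Each vertex is an excitable unit: an arriving pulse makes it fire
instantaneously unless it fired within the last ``delta`` time units (the
refractory period), in which case the pulse is discarded.  A firing at time
t schedules one future arrival per out-edge at t + lag.  Dynamics are run
by popping the earliest pending arrival from a priority queue, so the cost
is O(log E) per event regardless of how sparse the spiking is.

Conventions (fixed so the dynamics are deterministic):

* refractory window after a spike at t is the half-open [t, t + delta); an
  arrival at exactly t + delta fires, making delta the attainable minimum
  inter-spike interval;
* simultaneous arrivals are processed in ascending target-vertex order; two
  coincident arrivals at one vertex cause a single spike (the second lands
  inside the new refractory window);
* the kick start is a forcing-type arrival at t = 0 at ``kick_vertex``;
  under periodic forcing the t = 0 pulse plays that role and further pulses
  arrive every ``p`` units at the forced vertex, subject to the same
  refractory rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from heapq import heappop, heappush
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError, ParameterError
from .graphs import DirectedGraph, LagMap

__all__ = [
    "SimConfig",
    "SpikeHistory",
    "DIED_OUT",
    "REACHED_CAP",
    "REACHED_HORIZON",
    "run_free",
    "run_forced",
    "interspike_intervals",
    "mean_isi_per_vertex",
    "write_spikes_tsv",
    "read_spikes_tsv",
]

DIED_OUT = "died_out"
REACHED_CAP = "reached_cap"
REACHED_HORIZON = "reached_horizon"

DEFAULT_MAX_SPIKES = 100_000


@dataclass(frozen=True)
class SimConfig:
    """Simulation controls.

    delta       refractory period (> 0, time units)
    kick_vertex vertex receiving the t = 0 start-up pulse
    max_spikes  cap on total recorded spikes across all vertices
    t_max       optional time horizon (events after it are not processed)
    """

    delta: float
    kick_vertex: int = 0
    max_spikes: int = DEFAULT_MAX_SPIKES
    t_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ParameterError("refractory period delta must be positive")
        if self.max_spikes < 1:
            raise ParameterError("max_spikes must be at least 1")


@dataclass
class SpikeHistory:
    """Per-vertex strictly increasing firing times plus a terminal status."""

    times: list  # list of np.ndarray, one per vertex
    status: str

    @property
    def n(self) -> int:
        return len(self.times)

    def spike_count(self) -> int:
        return int(sum(len(t) for t in self.times))

    def events(self) -> np.ndarray:
        """All spikes as an (N, 2) array of (time, vertex) rows in global
        processing order (time ascending, ties by vertex)."""
        pairs = [
            (t, v) for v, ts in enumerate(self.times) for t in ts
        ]
        pairs.sort()
        return np.asarray(pairs, dtype=float).reshape(-1, 2)


def _out_table(g: DirectedGraph, lags: LagMap) -> list:
    out = [[] for _ in range(g.n)]
    for i, j in g.edges:
        if (i, j) not in lags:
            raise ConfigurationError(f"edge ({i}, {j}) has no transmission lag")
        lag = lags[i, j]
        if lag <= 0:
            raise ConfigurationError(f"edge ({i}, {j}) has non-positive lag")
        out[i].append((lag, j))
    for row in out:
        row.sort(key=lambda p: p[1])
    return out


def _run(
    g: DirectedGraph,
    lags: LagMap,
    cfg: SimConfig,
    period: Optional[float],
    force_vertex: Optional[int],
) -> SpikeHistory:
    n = g.n
    if not (0 <= cfg.kick_vertex < n):
        raise ParameterError("kick_vertex out of range")
    out = _out_table(g, lags)

    heap: list = []
    if period is None:
        heappush(heap, (0.0, cfg.kick_vertex))
        next_pulse = None
    else:
        if period <= 0:
            raise ParameterError("forcing period must be positive")
        if not (0 <= force_vertex < n):
            raise ParameterError("force_vertex out of range")
        next_pulse = 0.0

    last = [None] * n
    times: list = [[] for _ in range(n)]
    total = 0
    delta = cfg.delta
    t_max = cfg.t_max
    status = DIED_OUT

    while True:
        # lazily inject forcing pulses that are due before the queue head
        if next_pulse is not None:
            while next_pulse is not None and (
                not heap or next_pulse <= heap[0][0]
            ):
                if t_max is not None and next_pulse > t_max:
                    next_pulse = None
                    break
                heappush(heap, (next_pulse, force_vertex))
                next_pulse += period
        if not heap:
            status = DIED_OUT
            break
        t, v = heappop(heap)
        if t_max is not None and t > t_max:
            status = REACHED_HORIZON
            break
        lv = last[v]
        if lv is None or t - lv >= delta:
            last[v] = t
            times[v].append(t)
            total += 1
            for lag, w in out[v]:
                heappush(heap, (t + lag, w))
            if total >= cfg.max_spikes:
                status = REACHED_CAP
                break
        # else: arrival inside [last, last+delta) -> discarded

    return SpikeHistory([np.asarray(ts, dtype=float) for ts in times], status)


def run_free(g: DirectedGraph, lags: LagMap, cfg: SimConfig) -> SpikeHistory:
    """Free-running dynamics: one kick pulse at t = 0 at ``cfg.kick_vertex``,
    then the network drives itself until the spike cap, the horizon, or an
    empty queue (died out)."""
    return _run(g, lags, cfg, None, None)


def run_forced(
    g: DirectedGraph,
    lags: LagMap,
    cfg: SimConfig,
    p: float,
    force_vertex: int,
) -> SpikeHistory:
    """Periodically forced dynamics: pulses at 0, p, 2p, ... arrive at
    ``force_vertex`` (the t = 0 pulse doubles as the kick).  Pulses landing
    in a refractory window have no effect."""
    return _run(g, lags, cfg, p, force_vertex)


def interspike_intervals(
    h: SpikeHistory, vertex: int, burn_in_fraction: float = 0.0
) -> np.ndarray:
    """Consecutive firing-time differences at one vertex after discarding
    the first ``floor(burn_in_fraction * count)`` spikes."""
    if not (0 <= burn_in_fraction < 1):
        raise ParameterError("burn_in_fraction must lie in [0, 1)")
    t = h.times[vertex]
    drop = int(math.floor(burn_in_fraction * len(t)))
    t = t[drop:]
    if len(t) < 2:
        raise InsufficientDataError(
            f"vertex {vertex} has {len(t)} spikes after burn-in; need >= 2"
        )
    return np.diff(t)


def mean_isi_per_vertex(
    h: SpikeHistory, burn_in_fraction: float = 0.0
) -> np.ndarray:
    """Arithmetic mean inter-spike interval per vertex (post burn-in)."""
    return np.asarray(
        [
            interspike_intervals(h, v, burn_in_fraction).mean()
            for v in range(h.n)
        ]
    )


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------


def write_spikes_tsv(path, h: SpikeHistory) -> None:
    """Write `time  vertex` rows sorted by time, with the vertex count and
    terminal status as trailing comments."""
    path = Path(path)
    ev = h.events()
    with open(path, "w") as fh:
        fh.write("time\tvertex\n")
        for t, v in ev:
            fh.write(f"{float(t)!r}\t{int(v)}\n")
        fh.write(f"# n: {h.n}\n")
        fh.write(f"# status: {h.status}\n")


def read_spikes_tsv(path) -> SpikeHistory:
    path = Path(path)
    status = DIED_OUT
    n = None
    with open(path) as fh:
        lines = fh.readlines()
    rows = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "status:" in line:
                status = line.split("status:")[1].strip()
            elif "n:" in line:
                n = int(line.split("n:")[1].strip())
            continue
        if line.startswith("time"):
            continue
        t_str, v_str = line.split("\t")
        rows.append((float(t_str), int(v_str)))
    if n is None:
        n = 1 + max((v for _, v in rows), default=0)
    times: list = [[] for _ in range(n)]
    for t, v in rows:
        times[v].append(t)
    return SpikeHistory([np.asarray(ts, dtype=float) for ts in times], status)
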