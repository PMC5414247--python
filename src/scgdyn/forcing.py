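"""Periodic forcing scans and K:1 entrainment classification.

A network forced with period p is *entrained K:1* when its long-run
response is periodic with period K*p.  The classifier operationalises
"settles to a period of length Kp" as a phase-clustering test on the tail
of the probe vertex's spike train: let c be the number of tail spikes in
the first window of length P = K*p; periodicity with period P means
t[i + c] = t[i] + P for every tail spike, and the classifier accepts K when
the worst deviation from that identity is within ``tol`` time units.  K is
scanned in ascending order, so the reported K is minimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .graphs import DirectedGraph, LagMap
from .simulate import SimConfig, SpikeHistory, run_forced

__all__ = [
    "ENTRAINED",
    "NOT_ENTRAINED",
    "EntrainmentResult",
    "classify_spike_times",
    "classify_entrainment",
    "scan_periods",
]

ENTRAINED = "entrained"
NOT_ENTRAINED = "not_entrained"

DEFAULT_K_MAX = 8
DEFAULT_TOL = 1.0
DEFAULT_TAIL_FRACTION = 0.25


@dataclass(frozen=True)
class EntrainmentResult:
    status: str
    K: Optional[int] = None
    phase_spread: Optional[float] = None

    @property
    def entrained(self) -> bool:
        return self.status == ENTRAINED


def classify_spike_times(
    t,
    p: float,
    K_max: int = DEFAULT_K_MAX,
    tol: float = DEFAULT_TOL,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
) -> EntrainmentResult:
    """Entrainment test on a raw spike-time sequence (see module docstring)."""
    if p <= 0:
        raise ParameterError("forcing period p must be positive")
    if not (0 < tail_fraction <= 1):
        raise ParameterError("tail_fraction must lie in (0, 1]")
    t = np.asarray(t, dtype=float)
    start = int(math.floor((1.0 - tail_fraction) * len(t)))
    tail = t[start:]
    if len(tail) < 2:
        raise InsufficientDataError(
            f"only {len(tail)} spikes in the tail window; need >= 2"
        )
    for K in range(1, K_max + 1):
        P = K * p
        # spikes in the half-open reference window [tail[0], tail[0] + P)
        c = int(np.searchsorted(tail, tail[0] + P, side="left"))
        if c < 1 or len(tail) < c + 1:
            continue
        dev = float(np.abs(tail[c:] - tail[:-c] - P).max())
        if dev <= tol:
            return EntrainmentResult(ENTRAINED, K, dev)
    return EntrainmentResult(NOT_ENTRAINED)


def classify_entrainment(
    h: SpikeHistory,
    p: float,
    probe_vertex: int,
    K_max: int = DEFAULT_K_MAX,
    tol: float = DEFAULT_TOL,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
) -> EntrainmentResult:
    """Entrainment of a simulated history, observed at ``probe_vertex``."""
    return classify_spike_times(
        h.times[probe_vertex], p, K_max=K_max, tol=tol,
        tail_fraction=tail_fraction,
    )


def scan_periods(
    g: DirectedGraph,
    lags: LagMap,
    cfg: SimConfig,
    p_grid: Sequence[float],
    probe_vertex: int = 0,
    force_vertex: Optional[int] = None,
    K_max: int = DEFAULT_K_MAX,
    tol: float = DEFAULT_TOL,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
):
    """Force the network at each period of an increasing grid and classify
    the response.  Returns a list of (p, EntrainmentResult)."""
    p_grid = [float(p) for p in p_grid]
    if any(b <= a for a, b in zip(p_grid, p_grid[1:])):
        raise ParameterError("p_grid must be strictly increasing")
    if force_vertex is None:
        force_vertex = probe_vertex
    results = []
    for p in p_grid:
        h = run_forced(g, lags, cfg, p, force_vertex)
        try:
            res = classify_entrainment(
                h, p, probe_vertex, K_max=K_max, tol=tol,
                tail_fraction=tail_fraction,
            )
        except InsufficientDataError:
            res = EntrainmentResult(NOT_ENTRAINED)
        results.append((p, res))
    return results
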