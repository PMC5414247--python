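"""Size survey of the embedding dimension: sampling P(m | n, X).

For each network size n, sample ``replicates`` random z-regular SCGs, run
the free dynamics from a kick at vertex 0, and estimate the embedding
dimension m from the probe vertex's inter-spike intervals.  The conditional
distribution of m given n (and everything else held fixed: z, delta, lag
bounds, k) is summarised by its five-number summary per n, which is the
box-plot view showing m growing sublinearly with n.

Dynamics that die out before accumulating enough post-burn-in intervals
are recorded with ``survived = False`` and excluded from summaries, keeping
the distribution conditioned on sustained activity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .embedding import DEFAULT_WINDOW, embedding_dimension
from .errors import InsufficientDataError, ParameterError
from .graphs import GenParams, generate_scg_with_lags, graph_diameter
from .simulate import DIED_OUT, SimConfig, interspike_intervals, run_free

__all__ = [
    "SurveyParams",
    "SurveyRecord",
    "child_seed",
    "run_survey",
    "summarize",
]


@dataclass(frozen=True)
class SurveyParams:
    """Survey conditions. Defaults are the large-survey study conditions:
    delta = 30, z = 3, lags Uniform[50, 100], k = 80, 100 replicates."""

    n_values: Sequence[int]
    replicates: int = 100
    z: int = 3
    delta: float = 30.0
    lag_low: float = 50.0
    lag_high: float = 100.0
    k: int = DEFAULT_WINDOW
    burn_in: float = 0.2
    max_spikes: Optional[int] = None  # default: spikes_per_vertex * n
    spikes_per_vertex: int = 2500
    seed: int = 0
    n_swaps: Optional[int] = None  # default: 10 * n * z per graph
    min_intervals: Optional[int] = None  # default: 5 * (k + 1)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ParameterError("need at least one replicate")
        if not self.n_values:
            raise ParameterError("n_values must be non-empty")


@dataclass(frozen=True)
class SurveyRecord:
    n: int
    rep: int
    seed: int
    survived: bool
    m: Optional[int]
    significant: Optional[bool]
    diameter: int
    mean_isi: float
    status: str


def child_seed(master_seed: int, n: int, rep: int) -> int:
    """Stable per-replicate seed: SHA-256 of (master, n, rep), folded below
    2^31 so any subset of the survey is independently reproducible."""
    digest = hashlib.sha256(f"{master_seed}:{n}:{rep}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


def _swap_budget(params: SurveyParams, n: int) -> int:
    if params.n_swaps is not None:
        return params.n_swaps
    return 10 * n * params.z


def _spike_budget(params: SurveyParams, n: int) -> int:
    # run length scales with n so the probe vertex accumulates a fixed
    # observation count (~spikes_per_vertex) regardless of network size;
    # estimates are stable under doubling of this budget
    if params.max_spikes is not None:
        return params.max_spikes
    return params.spikes_per_vertex * n


def run_survey(params: SurveyParams):
    """One SurveyRecord per (n, replicate); deterministic in the master seed."""
    required_if_died = (
        params.min_intervals
        if params.min_intervals is not None
        else 5 * (params.k + 1)
    )
    records = []
    for n in params.n_values:
        n_swaps = _swap_budget(params, n)
        for rep in range(params.replicates):
            cs = child_seed(params.seed, n, rep)
            gp = GenParams(n=n, z=params.z, n_swaps=n_swaps, seed=cs)
            g, lags = generate_scg_with_lags(
                gp, params.lag_low, params.lag_high
            )
            cfg = SimConfig(
                delta=params.delta, kick_vertex=0,
                max_spikes=_spike_budget(params, n),
            )
            h = run_free(g, lags, cfg)
            diameter = graph_diameter(g)
            try:
                q = interspike_intervals(h, 0, params.burn_in)
            except InsufficientDataError:
                q = np.empty(0)
            # died-out runs need a healthy margin of intervals; sustained
            # runs just need enough to fill the embedding window
            needed = (
                required_if_died if h.status == DIED_OUT else params.k + 1
            )
            survived = len(q) >= needed
            m = significant = None
            if survived:
                est = embedding_dimension(q, params.k)
                m, significant = est.m, est.significant
            records.append(
                SurveyRecord(
                    n=n,
                    rep=rep,
                    seed=cs,
                    survived=survived,
                    m=m,
                    significant=significant,
                    diameter=diameter,
                    mean_isi=float(q.mean()) if len(q) else float("nan"),
                    status=h.status,
                )
            )
    return records


def records_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def summarize(records) -> pd.DataFrame:
    """Five-number summary (linear-interpolation quartiles) of m per n over
    surviving records; n with no survivors get count 0 and NaN statistics."""
    frame = records_frame(records)
    rows = []
    for n, group in frame.groupby("n", sort=True):
        m = group.loc[group["survived"], "m"].astype(float)
        if len(m) == 0:
            rows.append(
                dict(n=n, count=0, median=np.nan, q1=np.nan, q3=np.nan,
                     min=np.nan, max=np.nan)
            )
            continue
        rows.append(
            dict(
                n=n,
                count=int(len(m)),
                median=float(np.median(m)),
                q1=float(np.percentile(m, 25)),
                q3=float(np.percentile(m, 75)),
                min=float(m.min()),
                max=float(m.max()),
            )
        )
    return pd.DataFrame(rows)
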