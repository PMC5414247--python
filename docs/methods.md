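# Methods

`scgdyn` studies what a strongly connected directed graph (SCG) of
excitable-refractory units can *do* dynamically: how rich its long-run
firing behaviour is, how that richness scales with network size, and when
periodic input entrains it.  This note records the model, the estimators,
the tunable parameters with their defaults, and the design choices made
where the problem left them open.

## Dynamical model

A network is a simple directed graph on `n` vertices with no self-loops and
at most one edge per ordered pair.  Each vertex is an idealised neuron:

* a spike is instantaneous (pulse width is negligible against the
  transmission delays);
* after firing at time `t` the vertex is refractory on the half-open
  window `[t, t + δ)` and discards any arriving pulse; an arrival at
  exactly `t + δ` fires, so δ is the attainable minimum inter-spike
  interval (ISI);
* a spike at vertex `i` schedules one arrival per out-edge `(i, j)` at
  `t + l_ij`, where the transmission lag `l_ij > 0` is fixed per edge,
  drawn i.i.d. Uniform(low, high).

Dynamics start from a single kick pulse at `t = 0` at one vertex, or, under
periodic forcing, from pulses at `0, p, 2p, …` injected at a forced vertex
subject to the same refractory rule.  Because spikes are point events, the
whole dynamic is advanced exactly by a priority queue of pending arrivals
(O(log E) per event); there is no integration error and no time grid.
Simultaneous arrivals are processed in ascending target-vertex order; two
coincident arrivals at one vertex cause one spike.  A run ends at a spike
cap, a time horizon, or when the queue empties (`died_out` — every pending
return landed in a refractory window).

These boundary/tie conventions are declared, not derived: the underlying
idealisation does not fix them, and any fixed choice makes the dynamics
deterministic.  The independent cross-check in the test suite (a brute-force
10⁻³-resolution time-stepping simulator, compared spike for spike on dyadic
rational lags so both arithmetics are exact) uses the same conventions.

## Sampling strongly connected z-regular graphs

Random graphs of prescribed mean degree are rarely strongly connected, so
the sampler random-walks inside the set of z-regular SCGs:

1. **Seed**: traverse one random cyclic order of the vertices with each of
   the first `z` strides coprime to `n`.  Each stride is a Hamiltonian
   cycle, distinct strides are edge-disjoint, so the union has every
   in- and out-degree exactly `z` and is strongly connected.  This permuted
   circulant is deliberately contrived — "long and thin", diameter of order
   `n/z` (≈16 at n=100, z=3).  (If `n` has fewer than `z` coprime strides,
   the remainder are independent random Hamiltonian cycles with
   disjointness retries; the corner cases (n, z) = (4, 3) and (6, 5) are
   provably infeasible — no Hamiltonian decomposition of K*₄ or K*₆ exists —
   and raise a generation error.)
2. **Chain**: repeat double-edge swaps `(a,b),(c,d) → (a,d),(c,b)` with the
   picked edges vertex-disjoint in the swapped positions; reject a proposal
   if it would duplicate an edge or break strong connectivity (checked by
   two depth-first searches, forward and edge-reversed).  Swaps preserve
   every vertex's degrees, so the chain stays inside the z-regular SCG set
   and relaxes toward homogeneous random regular digraphs; the diameter
   falls to its typical random value (≈6 at n=100, z=3) within a few
   thousand attempts.

`n_swaps` counts *attempts* (rejection is part of the chain).  The default
chain length where none is given is `10·n·z` attempts (~20 proposals per
edge), after which the diameter has long plateaued.  Topology and lag draws
come from independent child streams of one master seed, so the same seed
yields the same graph whether or not lags are used.

## Embedding-dimension estimation

The observable is the ISI sequence `q` at a single probe vertex after
discarding the first 20% of its spikes (burn-in; the long-run attractor,
not the transient, is the object of interest).  Singular spectrum analysis
is applied to `q` itself — the event-time analogue of delay-coordinate
embedding for evenly sampled signals:

* trajectory matrix `X`: rows are the `N = len(q) − k + 1` sliding windows
  of `k` successive intervals (Hankel structure), default `k = 80`, with
  the embedding delay fixed at one interval;
* spectrum: eigenvalues of the uncentered second-moment matrix
  `C = XᵀX/N`, sorted descending, round-off negatives clamped to zero.
  Uncentered is deliberate: the constant (mean-ISI) component counts as one
  dimension, so a perfectly periodic system reports `m = 1` and a winding
  dynamic on a μ-torus, which embeds in `R^(μ+1)`, reports `m ≈ μ + 1`;
* break detection: eigenvalues below `10⁻¹²·λ₁` are clamped to that floor;
  the estimate `m` is the *last* position whose log-gap
  `ln λ_i − ln λ_{i+1}` exceeds θ = 2 natural-log units — the point where
  the spectrum finally drops to the noise/round-off floor, bounding the
  whole deterministic subspace.  Taking the single largest gap instead
  would latch onto the mean component's gap (`≈ ln(k·μ²/σ²)`, 11–13 ln
  units when ISIs sit just above δ) and report `m = 1` for manifestly
  structured dynamics.  When no gap clears θ the spectrum is a
  decay/plateau with no significant break (the signature of noise); `m`
  falls back to the largest gap, ties toward the smallest index, flagged
  `significant = False`.

θ and the floor ratio are package parameters with no counterpart in the
underlying theory; θ = 2 separates the structural breaks seen in practice
(≥ 4 ln units) from plateau fluctuations (≤ 1).  One caveat of the
uncentered convention: i.i.d. positive noise with a large mean carries a
genuine rank-1 constant component and is reported as a *significant*
`m = 1`; only fluctuation-dominated noise (coefficient of variation ≳ 3)
shows the pure plateau.  Downstream analyses should read `m = 1` as
"constant plus unresolved fluctuation", not as evidence of a limit cycle.

Exactness matters here: because the simulator is event-exact, a genuinely
low-dimensional attractor drives the spectrum tail to round-off level
(~`eps·λ₁`), which is what makes the break detectable at all.

## Entrainment classification

A forced system is entrained `K:1` when its response settles to period
`K·p`.  The classifier takes the final 25% of the probe vertex's spikes,
counts the spikes `c` in the first window of length `P = K·p`, and accepts
`K` (scanned ascending, so the reported `K` is minimal) when
`max_i |t[i+c] − t[i] − P| ≤ tol` over the whole tail.  Defaults:
`K_max = 8`, `tol = 1.0` time units, tail fraction 0.25.  This is an
operationalisation chosen here — "settles to period Kp" has no canonical
test — and it is exact on constructed periodic trains, monotone in `tol`,
and rejects irrational rotations at any `K`.  Scans report `not_entrained`
for the gaps without distinguishing higher-order locking from chaos, which
a finite spike train cannot decide.

## The size survey

`P(m | n, X)` is sampled by, for each size `n` and replicate: derive a
child seed (SHA-256 of master seed, `n`, replicate — any subset of the
survey is independently reproducible), sample a graph and lags, run the
free dynamics from vertex 0, and estimate `m` at vertex 0.  Study
conditions (defaults): δ = 30, z = 3, lags U[50, 100], k = 80, burn-in
20%, 100 replicates (scaled-down runs use 20).

Run length is the one parameter with no stated value anywhere: the spike
cap defaults to `2500·n`, giving the probe vertex ~2000 post-burn-in
intervals at every size.  This was fixed by a stability analysis — at
n = 100 and 200 the estimates are unchanged under a 2× longer budget,
while a flat cap leaves large networks with a few hundred windows and
unresolved spectra.  Runs that die out before 5·(k+1) post-burn-in
intervals are recorded `survived = False` and excluded from summaries,
conditioning `P(m | n, X)` on sustained activity; sustained runs need only
`k + 1` intervals to be embeddable.  Summaries are per-size five-number
summaries of `m` (linear-interpolation quartiles).

Observed behaviour: per-size `m` distributions are wide (IQR roughly
7–25 at n = 100), so a 20-replicate median carries sampling error of a few
units; the growth of the median with `n` is robust (e.g. 60-replicate
medians 11 at n = 50 vs 13.5 at n = 100) but adjacent sizes can invert in
any single 20-replicate draw.  Scaling tests therefore assert the trend
(all larger sizes above the smallest, positive median-vs-ln n slope,
decelerating growth, ratio far below proportionality), not adjacent-pair
ordering.

## What the generator does and does not emulate

All inputs are synthetic by design — the object of study is the model
class itself, not recorded data.  The generator produces exactly z-regular
graphs (real neuronal graphs have degree heterogeneity), uniform
independent lags (real conduction delays correlate with axon length), and
deterministic loss-free transmission (no synaptic failure, no inhibition,
no amplitude dynamics).  Passing tests therefore demonstrate properties of
the idealised excitable-refractory-delay dynamic on homogeneous SCGs;
they do not establish that biological sub-circuits realise these numbers,
only that the qualitative conclusions (low-dimensional toroidal attractors,
sublinear growth of dimension with size, selective entrainment windows) are
forced by the architecture class.

## Numerical choices and degenerate inputs

* Times are double-precision floats; no rounding is applied anywhere.
* Graphs with `n = 1` are valid (trivially strongly connected, diameter 0);
  `n = 0` is rejected.
* `low == high` lag bounds are the degenerate point mass.
* A swap proposal that cannot find a constraint-satisfying edge pair in 100
  picks counts as a rejected attempt (relevant only for graphs, like a pure
  directed cycle, where essentially no admissible swap exists).
* `detect_break` raises on an all-zero spectrum; `interspike_intervals`
  raises when fewer than two spikes survive the burn-in.
* Quartiles use linear interpolation (numpy's default percentile).

## Known limitations

* The entrainment test examines one probe vertex; spatially distributed
  locking patterns are out of scope.
* `m` is an upper bound for the attractor dimension μ, biased upward by
  +1 (mean component) and downward when the run is too short for the
  spectrum tail to reach the floor; the scaled cap controls the latter at
  surveyed sizes but extreme sizes would need their own stability check.
* The swap chain is not a uniform sampler of z-regular SCGs (connectivity
  rejection biases it); it matches the intended use — generating diverse,
  homogeneous strongly connected instances — not exact uniformity.
* Forcing scans hold the forcing phase fixed at the kick; phase offsets
  between forcing and internal cycles are not scanned.
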