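# Methods

## Problem and model

A single node of a static, simple, undirected, unweighted, connected
contact network becomes infected at t = 0. The spread follows a
discrete-time compartmental model, and at some unknown later time an
observation of node statuses is taken. The task is to infer the source
node from that one observation, without knowing the elapsed time or, for
the identifiers, the propagation parameters.

### Propagation

Updates are synchronous (generation-based). At each step:

* every susceptible node with j neighbours that *entered the step*
  infectious becomes infected with probability 1 − (1 − β)^j — one
  independent Bernoulli(β) trial per infectious neighbour;
* under SIR, every node that entered the step infectious recovers with
  probability γ; recovery is absorbing.

A node infected within a step can neither transmit nor recover until the
next step. The simulation stops at the first step where the ever-infected
fraction |I ∪ R|/n reaches `stop_fraction`; recovered nodes count as
infected both here and in every observation (the SIR model is folded into
SI by treating R as I — whether "30% infected" should count R is not
dictated by the model, and counting I ∪ R keeps SI and SIR protocols
comparable). A spread that cannot reach the threshold within `max_steps`
(default 10·n) — β = 0, or an SIR die-out — raises a typed error carrying
the partial outcome rather than returning silently.

Defaults mirror the benchmark protocol: β = 0.3, γ = 0.1,
`stop_fraction` = 0.3.

### Observations

* **Complete**: every node reports infected (I or R) or uninfected (S).
* **Uniform snapshot**: round(r·n) nodes (round half away from zero),
  sampled uniformly without replacement, report their true status; the
  rest are unknown. Draws are rejected until both statuses appear among
  the revealed nodes, so downstream restoration is never degenerate by
  construction; r = 1 reduces to the complete observation.
* **Infected-only snapshot**: exactly the ever-infected nodes are
  reported (as infected), everything else is unknown. Recovered nodes are
  exposed as infected, consistent with the I/R unification; whether a
  recovered individual would be observable in practice is scenario
  dependent, and this choice keeps the snapshot an exact image of the
  infection subgraph.

## Label ranking

With initial labels y (infected → b = +1, uninfected → a = −1, unknown →
0), scores evolve as f ← α·M f + (1 − α)·y and converge to
f\* = (1 − α)(I − α M)^(−1) y; since the spectral radius of every
supported M is 1, the system is nonsingular for α < 1 and the iteration
is a contraction. The fixed point minimises a quadratic cost combining a
degree-normalised smoothness term over edges with a fitting term toward
y; α ≈ 0.5 balances the two and is the default (the benchmark sweep in
the acceptance suite confirms the error distance is minimised near 0.5
against the 0.1 and 0.9 extremes).

Matrix kinds: `SYM` (D^(−1/2)WD^(−1/2), default — the degree
normalisation prevents high-degree hubs from being dominated by their
many low-degree neighbours), `ROW` (D^(−1)W) and `COL` (its transpose).

Numerical choices:

* Stop rule ‖f(k+1) − f(k)‖₂ ≤ `tol_scale`·n with `tol_scale` = 10⁻⁴; the
  n-scaling keeps the criterion comparable across network sizes. On the
  200-node benchmarks this converges in ~6 sweeps. Test oracles tighten
  `tol_scale` to 10⁻¹² and compare against the direct sparse solve to
  10⁻⁶, isolating iteration truncation from modelling differences.
* Non-convergence within `max_iter` returns the last iterate flagged
  `converged=False` instead of raising — the consumer is an argmax.
* Argmax ties break to the lowest node id (deterministic replay).
* BLRSI restricts the argmax to observed-infected nodes; VLRSI does not.
  The label weights (a, b) are configurable — harsher uninfected
  punishment such as (−2, +1) raises the detection rate on scale-free
  networks — but (0, 0) is rejected.
* The smoothness/fitting trade-off is exposed only through α; no separate
  regularisation weight is surfaced, matching the iterative algorithms as
  used.

## Network-status restoration

Stage one of the two-stage pipeline treats restoration as semi-supervised
binary classification with soft-label matrix F (n×2; column 0 uninfected,
column 1 infected) initialised from the one-hot matrix Y:

* **GFHF**: F ← P·F with P = D^(−1)W, observed rows re-clamped to Y every
  sweep. The unobserved block solves the harmonic system
  F_U = (I − P_UU)^(−1) P_UL Y_L (kept as a test oracle); by the maximum
  principle each soft row is a convex combination of the observed one-hot
  rows.
* **LGC**: F ← α·S·F + (1 − α)·Y, no clamping, α = 0.5 default. Observed
  nodes are classified from F like all others, which lets the restoration
  override a noisy report.

Classification is the row argmax; an exact tie classifies as uninfected
(conservative for source candidacy — configurable via `tie_break`).
Restoring from a snapshot whose observed set contains a single class is
refused with a typed error: every unlabelled node would collapse onto
that class. GFHF is implemented iteratively with clamping (not via the
Schur-complement closed form) so its cost stays O(k·m).

Stage two runs BLRSI on the restored complete observation with default
weights and the symmetric normalisation.

## Evaluation harness

Per run: a source is drawn uniformly, a spread simulated, the configured
observation built, the configured identifier applied. Reported metrics:
detection rate (exact-match fraction), average error distance (mean
geodesic hops between inferred and true source), an error-distance
histogram, and — for two-stage runs — the mean restoration F1 with
infected as the positive class, evaluated on unobserved nodes by default
(observed nodes are trivially correct under clamping; the node set is
configurable). Wall-clock time is informational only.

Seeding: each run's random streams derive from
`SeedSequence((master_seed, run_index, attempt))`. SIR die-outs are
redrawn (source and trajectory) on the next `attempt` substream and
counted; a redraw rate above 10% is flagged in the report. Because
streams are keyed, sweeps over α, r or the label weights reuse identical
propagation outcomes across swept values — paired comparisons that
isolate the parameter effect.

## Synthetic benchmark networks

The harness regenerates the three standard random-graph families at the
published sizes: ER G(n, m) with n = 200, m = 1247 (the fixed-edge-count
variant, so the printed edge count is matched exactly), BA with
attachment 6 (194·6 = 1164 edges; growth from a star over the first
m+1 nodes makes the count deterministic), and WS with ring degree 12
(1200 edges). ER and WS are redrawn until connected (cap 1000 attempts)
rather than trimmed, keeping n exact.

The WS rewiring probability is not part of the published table; it is set
to 0.2, the smallest value at which the generated instances consistently
reach the published diameter of 4 (at 0.1 the diameter is 5) while
staying in the small-world regime. It is configurable.

What the generators do *not* emulate: real contact networks have
community structure, degree correlations, temporal edges and weighted
contacts. Passing benchmarks on ER/BA/WS therefore demonstrates
correctness of the machinery and reproduction of the published synthetic
results, not field performance; real edge lists can be supplied through
the same reader.

Benchmark problem sizes: 1000 Monte-Carlo runs per table cell and 500
paired runs per sweep point, the sizes the reported results are averaged
over.

## Known limitations

* Single source only; no multi-source ranking.
* SI/SIR only — no SIS, no continuous time, no per-edge rates, no sensor
  (timestamped) observations.
* The identifiers are heuristics: scores are diffusion ranks, not
  posterior probabilities, and detection rates on these problems are
  intrinsically low (≤ ~0.3); error distance is the more informative
  metric.
* Restoration is binary (infected/uninfected); no multi-class or
  embedding-based restorers.
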