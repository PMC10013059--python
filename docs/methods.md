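# Methods

## Model

Agents are n oscillators with identical periods on a planar integer grid.
Each carries a strategy (s, φ): a communication flag s ∈ {C, N} and a phase
index φ ∈ {1..d} on the cycle of d evenly spaced phases.  Payoffs depend
only on the two flags and the cyclic index distance
k(q, r) = min(|q−r|, d−|q−r|) ∈ {0..⌊d/2⌋}:

|            | partner C        | partner N        |
|------------|------------------|------------------|
| focal C    | −c + B(k)        | −c + β(k)        |
| focal N    | β(k)             | 0                |

with linear benefits B(k) = B(0)(1 − k/d) and β(k) = β(0)(1 − k/d),
B(0) ≥ β(0) ≥ 0 so that communicators never earn less than free-riders at
equal distance.  The full 2d × 2d payoff matrix is indexed by the strategy
list ((C,φ₁)…(C,φ_d),(N,φ₁)…(N,φ_d)); entries give the payoff to the row
player, the all-N block is identically zero, and the table is invariant
under simultaneous rotation of both phase indices.

At equal phase the C/N interaction is a 2×2 game with R = B(0) − c,
S = β(0) − c, T = β(0), P = 0.  `classify_game` labels the region by the
signs of R − T = B(0) − β(0) − c and S − P = β(0) − c: mutualism (both
positive), snowdrift (R − T < 0 < S − P), coordination (S − P < 0 < R − T),
Prisoner's Dilemma (both negative).  Exact ties return `"boundary"`:
integer sweeps against c = 10 place pairs exactly on the region edges, and
silently absorbing them into a neighbor region would bias region-level
summaries.  The same-phase reduction is used because the death-birth
dynamics (below) evaluates competing flags at a common phase, so it is the
same-phase game that governs the observed outcomes.

## Death-birth dynamics

Each iteration one node i is chosen uniformly at random to die.  Every
neighbor j proposes a candidate — by default the pair (flag of j, phase of
i) — and the replacement is drawn with probability proportional to
exp(δ·π(i, candidate)), where π is the payoff the candidate strategy would
earn at node i against i's current neighborhood (the sum over neighbors;
`payoff_aggregation="mean"` switches to the per-neighbor average, which
only rescales the effective selection strength by the degree).  The
per-interaction cost uses node i's own c(i).  There is no mutation, so the
all-C and all-N flag configurations are absorbing: once the communicative
fraction p reaches 0 or 1 it can never change, and runs stop there.

Two design points deserve justification:

* **The candidate keeps the node's own phase** (``phase_inheritance="node"``,
  the default).  The phase is treated as the physical configuration of the
  oscillator occupying a site; what evolves is whether that oscillator
  communicates.  Under pure imitation of full (flag, phase) strategies
  (available as ``phase_inheritance="neighbor"``) only the two seeded
  strategies ever exist, so the population plays the single reduced game at
  the invader–resident phase distance d/2 — in that regime the mutualism
  region cannot be invaded at all (the lone invader earns
  deg·(β(0)/2 − c) < 0 throughout the region) and the snowdrift region
  fixes instead of mixing.  The default rule restores the same-phase game
  as the operative one and with it the three qualitative outcomes the
  region structure predicts: mutualism → full communication, snowdrift →
  persistent mixed states, Prisoner's Dilemma / coordination → rapid
  extinction of the invader.

* **Candidates are weighted by their potential payoff at the vacated node**,
  not by the proposing neighbor's own realized payoff.  Weighting by the
  neighbor's own payoff makes the invasion probability of a rare
  communicator scale like exp(−δ·deg·(c − β(d/2))) — effectively zero
  under the default selection strength — and again empties the mutualism
  region.

Fitness weights are always normalized in the log domain (max-subtracted
exponentials), so profiles stay finite even when δ·π exceeds the
floating-point exponent range (summed payoffs on the all-to-all topology
reach order n·B(0)).  Nodes with no neighbors (possible under the sparse
random topology) are inert: their death is a no-op, since there is no
neighborhood to define the profile.

Invasions start with every node silent at phase 1 and one node, chosen
uniformly, communicative at phase 1 + ⌊d/2⌋ — maximal cyclic distance, the
least favorable seed, since its neighbors evaluate communication through
the depressed benefit B(⌊d/2⌋).  The resident phase is fixed at 1 without
loss of generality (rotation invariance of the table).

## Topologies

Oscillators occupy a w × h grid, 1-based coordinates, row-major node
order.  Generators: all-to-all; 4-nearest-neighbor (axial, edge nodes omit
missing links); 8-nearest-neighbor (axial + diagonal); probabilistic
spatial, joining each unordered pair at Euclidean distance r exactly once,
independently, with probability 1/(r + γ).  The probabilistic form was
fixed by verification against the reported ensemble statistics: on the
40×40 grid at γ = 10 it reproduces both the average clustering coefficient
(≈0.038 vs the reported 0.0365) and the average path length (≈2.08, as
reported), which the squared-distance alternative 1/(r² + γ) misses by
factors of 2.4 and 1.7 respectively.  No single form also reproduces the
separately quoted mean degree of ~10 (the linear form gives ≈58); the
package keeps the form confirmed by the two-decimal metrics and reports
degree honestly.  Isolated nodes are counted and reported, never silently
regenerated.

Costs: uniform mode gives every node the base cost c (default 10);
degree-adjusted mode gives node i the cost c·N(i)/μ with μ the mean
degree, so the population mean cost equals c exactly and runs under the
two cost structures are comparable.  On regular graphs the modes coincide.

Metrics: the mean local clustering coefficient (triangles over neighbor
pairs, degree-<2 nodes counted as 0) is computed with sparse matrix
products and cross-checked against networkx in the tests; shortest paths
use scipy's C BFS, averaging over connected pairs and warning when the
graph is disconnected.

## Experiments

`run_sweep` executes the invasion protocol for every benefit pair
(B(0) ∈ {1..40}, β(0) ∈ {1..B(0)} by default — 820 pairs), a configurable
number of trials per pair (default 20) and iteration budget (default
50,000) on a 40×40 grid (n = 1,600), d = 10, δ = 1.  Fixed topologies are
built once; the probabilistic spatial topology is regenerated
independently per trial.  Per-trial seeds derive from
`SeedSequence((master, B0, β0, trial))`, decoupling pairs so partial
sweeps are exactly reproducible.  The headline per-pair statistics are the
final-iteration communicative fraction averaged over trials and the mean
convergence time, with non-converged trials contributing the budget as a
sentinel (a mean of 50,000 means no trial converged).  The
final-vs-time-averaged reading of the mixed-state statistic is genuinely
ambiguous, so the per-trial time average of p is stored alongside the
final value; the final value is the headline.

## Oracle validation

Restricted to the two flags on a frozen phase field, the process is an
absorbing Markov chain on the 2ⁿ flag assignments with exactly two
absorbing states.  For n ≤ 12 the transition operator is enumerated
exactly — through the same fitness-profile code the simulations use — and
invader fixation probabilities are obtained from the absorbing-chain
linear system (dense solve; state spaces ≤ 2¹²).  Tests require
Monte-Carlo fixation frequencies to match the exact values within three
standard errors across parameter regimes, and recover the neutral-drift
law (fixation 1/n for a single invader on vertex-transitive graphs at
B(0)=β(0)=0, c=0, where the update reduces to the voter model).  On a
small all-to-all system with B(0)=β(0)=b, exact fixation probabilities
switch from ≈0 below b = 2c to >0.8 above it (moderate selection,
δ = 0.1): the classical all-to-all threshold "benefit greater than twice
the cost" emerges from the implemented dynamics.

## Problem sizes and tolerances

The test suite exercises the full 40×40 protocol where the claim depends
on it (the 100-instance metric ensemble; the 20×50,000-iteration snowdrift
band) and documented scaled-down versions elsewhere: 12×12 grids for the
region-outcome comparisons, 20×20 for the convergence-speed ordering
(conditioning on runs that reach fixation, since failed invasions absorb
quickly and would otherwise flatter sparse topologies), n ≤ 8 for exact
chains.  Stochastic ensemble comparisons use ~10% relative tolerance or
three standard errors; exact identities (cost normalization, block zeros,
neutral fixation) use machine-precision bounds.

## Known limitations

* The model has no Kuramoto phase dynamics: phases are static strategy
  labels, and "synchronization" means strategy consensus, not entrainment
  of oscillator state.  External light input, weighted or directed
  coupling, and time-varying topologies are out of scope.
* Under the default update rule phases never change, so phase consensus
  dynamics (which phase wins) are not modeled — only the communication
  flag evolves.
* The synthetic topologies capture degree structure and spatial decay of
  connectivity, not the core/shell organization or cell-type heterogeneity
  of the real SCN; passing tests validate the game-theoretic mechanism,
  not anatomical realism.
* Mixed-state levels in the snowdrift region depend on the local degree
  (the interior equilibrium is pinned by neighborhood payoff crossings),
  so quantitative band positions transfer across topologies only
  approximately.
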