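"""Death-birth dynamics of the communication game on a fixed topology.

The update is a death-birth rule: each iteration one oscillator is chosen
uniformly at random to die, and the vacated node is refilled with a
strategy determined by the potential payoff of the available choices *at
that node*.  Each neighbor ``j`` proposes a candidate strategy and is
drawn with probability proportional to the exponential fitness
``f = exp(delta * pi)`` of that candidate against the dying node's own
neighborhood in the current configuration.  High-payoff strategies are
likely to win, but the randomness allows sub-optimal assignments.

What a candidate consists of is controlled by
``GameParameters.phase_inheritance``:

* ``"node"`` (default) — the candidate is (neighbor ``j``'s communication
  flag, the vacated node's own phase).  The phase is the physical
  configuration of the oscillator occupying that site; the trait under
  selection is whether it communicates.  Homogeneous-flag populations are
  then absorbing, a lone communicator at maximal phase distance really is
  the hardest seed (its neighbors evaluate communication through the
  depressed benefit ``B(d/2)``), and free-riders can coexist with
  communicators at the same phase — the anti-coordination (snowdrift)
  regime produces persistent mixed states.

* ``"neighbor"`` — the candidate is neighbor ``j``'s full (flag, phase)
  strategy, i.e. pure imitation.  Only the two seeded strategies then ever
  exist, so the population effectively plays the single reduced game at
  the invader-resident phase distance.

Runs start from a single-invader state: a homogeneous population of silent
oscillators at phase 1 plus one communicator at the maximally distant
phase.  The per-iteration communicative fraction ``p`` is recorded; ``p``
in {0, 1} is absorbing because there is no mutation, so runs stop early at
absorption.

Fitness weights are always normalized in the log domain (max-subtracted
exponentials), so selection stays well defined even when ``delta * pi``
exceeds the floating-point exponent range, e.g. on the all-to-all topology
where summed payoffs scale with ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .game import GameParameters, Strategy, build_payoff_table
from .topology import Topology

__all__ = [
    "PopulationState",
    "initialize_invasion",
    "expected_payoff",
    "candidate_payoffs",
    "fitness",
    "fitness_profile",
    "death_birth_step",
    "run_simulation",
]


@dataclass
class PopulationState:
    """Per-node strategies plus the recorded history of one run.

    ``codes[i]`` is the 0-based index of node ``i``'s strategy in the
    canonical strategy list (``C`` phases 0..d-1, then ``N`` phases
    d..2d-1).  ``trajectory[t]`` is the communicative fraction ``p`` after
    ``t`` iterations (``trajectory[0]`` is the initial state); after
    absorption the constant tail is implicit — only ``absorption_time`` and
    the final value are kept.
    """

    codes: np.ndarray = field(repr=False)
    d: int
    iteration: int = 0
    trajectory: list[float] = field(default_factory=list, repr=False)
    absorbed: bool = False
    absorption_time: int | None = None
    time_average_p: float | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if not self.trajectory:
            self.trajectory = [self.p]
        if self.p in (0.0, 1.0) and not self.absorbed:
            self.absorbed = True
            self.absorption_time = self.iteration

    @property
    def n(self) -> int:
        return self.codes.size

    @property
    def n_communicative(self) -> int:
        return int((self.codes < self.d).sum())

    @property
    def p(self) -> float:
        """Current communicative fraction."""
        return self.n_communicative / self.n

    def strategy_at(self, i: int) -> Strategy:
        return Strategy.from_code(int(self.codes[i]), self.d)

    @property
    def strategies(self) -> list[Strategy]:
        return [Strategy.from_code(int(c), self.d) for c in self.codes]


def invader_phase_index(d: int) -> int:
    """Phase maximally distant from phase 1 on the d-cycle: ``1 + d // 2``."""
    return 1 + d // 2


def initialize_invasion(
    topology: Topology, d: int, rng: np.random.Generator | int
) -> PopulationState:
    """All nodes silent at phase 1, except one uniformly chosen communicator
    at the maximally distant phase (cyclic distance ``d // 2``)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = topology.n
    if n < 2:
        raise ValueError(f"need at least 2 oscillators, got {n}")
    if d < 2:
        raise ValueError(f"need d >= 2, got {d}")
    resident = Strategy("N", 1).code(d)
    invader = Strategy("C", invader_phase_index(d)).code(d)
    codes = np.full(n, resident, dtype=np.int64)
    codes[int(rng.integers(n))] = invader
    return PopulationState(codes=codes, d=d)


def _node_cost(topology: Topology, params: GameParameters, i: int) -> float:
    if topology.node_costs is not None:
        return float(topology.node_costs[i])
    return params.cost


def _aggregate(total: float, deg: int, mode: str) -> float:
    return total / deg if mode == "mean" else total


def expected_payoff(
    state: PopulationState, params: GameParameters, topology: Topology, node: int
) -> float:
    """Expected payoff ``pi`` of ``node`` playing its current strategy: its
    payoff-table row accumulated over its neighbors (summed by default,
    averaged under ``payoff_aggregation='mean'``), with the focal node's
    own cost in the cost-bearing entries.  Zero if the node is isolated."""
    nb = topology.neighbors(node)
    if nb.size == 0:
        return 0.0
    table = build_payoff_table(params, node_cost=_node_cost(topology, params, node))
    total = float(table.entries[state.codes[node], state.codes[nb]].sum())
    return _aggregate(total, nb.size, params.payoff_aggregation)


def candidate_payoffs(
    state: PopulationState, params: GameParameters, topology: Topology, node: int
) -> np.ndarray:
    """Expected payoff at ``node`` of every candidate strategy.

    Entry ``s`` is the payoff strategy ``s`` (0-based canonical code) would
    earn at ``node`` against the node's current neighborhood, using the
    node's own cost.  This is the quantity the death-birth selection
    weighs: the potential payoff of each strategy *for the vacated node*.
    """
    nb = topology.neighbors(node)
    if nb.size == 0:
        raise ValueError(f"node {node} has no neighbors; candidate payoffs undefined")
    table = build_payoff_table(params, node_cost=_node_cost(topology, params, node))
    hist = np.bincount(state.codes[nb], minlength=2 * params.d)
    totals = table.entries @ hist
    if params.payoff_aggregation == "mean":
        return totals / nb.size
    return totals


def fitness(pi: float, delta: float) -> float:
    """Exponential fitness ``exp(delta * pi)``; 1 at neutral payoff or delta=0.

    May overflow to ``inf`` for extreme ``delta * pi``; selection code uses
    :func:`fitness_profile`, which normalizes in the log domain instead.
    """
    return float(np.exp(delta * pi))


def candidate_codes(
    state: PopulationState, params: GameParameters, node: int, neighbors: np.ndarray
) -> np.ndarray:
    """Strategy code each neighbor proposes for ``node`` on replacement:
    the neighbor's flag paired with the node's own phase under the default
    ``phase_inheritance='node'``, or the neighbor's full strategy under
    ``'neighbor'``."""
    s_nb = state.codes[neighbors]
    if params.phase_inheritance == "neighbor":
        return s_nb
    d = params.d
    own_phase = int(state.codes[node]) % d
    return np.where(s_nb < d, own_phase, own_phase + d)


def fitness_profile(
    state: PopulationState, params: GameParameters, topology: Topology, node: int
) -> tuple[np.ndarray, np.ndarray]:
    """Replacement distribution over ``node``'s neighbors.

    Returns ``(neighbor_indices, probabilities)``: neighbor ``j`` is chosen
    with probability proportional to ``exp(delta * pi)`` of the candidate
    strategy it proposes (see :func:`candidate_codes`), evaluated against
    the node's current neighborhood.  Neighbors proposing the same
    candidate share a weight, so two nodes with identical neighbor sets
    and equal phase have identical profiles.  Computed with
    max-subtraction so the result is finite for arbitrarily large payoffs.
    Raises on a neighborless node (the caller treats that death as a
    no-op).
    """
    nb = topology.neighbors(node)
    if nb.size == 0:
        raise ValueError(f"node {node} has no neighbors; fitness profile undefined")
    pis = candidate_payoffs(state, params, topology, node)
    log_w = params.delta * pis[candidate_codes(state, params, node, nb)]
    w = np.exp(log_w - log_w.max())
    return nb, w / w.sum()


def _select_from_weights(w: np.ndarray, rng: np.random.Generator) -> int:
    """Draw an index proportional to non-negative weights with one uniform."""
    cw = np.cumsum(w)
    return int(np.searchsorted(cw, rng.random() * cw[-1], side="right"))


def death_birth_step(
    state: PopulationState,
    params: GameParameters,
    topology: Topology,
    rng: np.random.Generator,
) -> PopulationState:
    """One death-birth iteration, in place: a uniformly chosen node is
    refilled with the candidate strategy of a neighbor drawn from its
    fitness profile.  A neighborless node's death is a no-op.  Payoffs are
    evaluated on the pre-replacement configuration.  Extends the
    trajectory by one entry."""
    i = int(rng.integers(state.n))
    nb = topology.neighbors(i)
    if nb.size > 0:
        cand = candidate_codes(state, params, i, nb)
        pis = candidate_payoffs(state, params, topology, i)
        log_w = params.delta * pis[cand]
        k = _select_from_weights(np.exp(log_w - log_w.max()), rng)
        state.codes[i] = cand[k]
    state.iteration += 1
    p = state.p
    state.trajectory.append(p)
    if not state.absorbed and p in (0.0, 1.0):
        state.absorbed = True
        state.absorption_time = state.iteration
    return state


class _Engine:
    """Vectorized death-birth stepper over a fixed topology.

    Per step it histograms the dying node's neighbor strategies, computes
    every candidate strategy's payoff with one (2d x 2d) mat-vec against
    the cost-free gain table, applies the node's cost term, and samples the
    replacement in the log domain — O(deg + d^2) per iteration regardless
    of the configuration, with no state beyond the strategy codes.
    """

    def __init__(self, topology: Topology, params: GameParameters):
        self.params = params
        self.d = params.d
        adj = topology.adjacency
        self.n = topology.n
        self.indptr = adj.indptr
        self.indices = adj.indices
        deg = topology.degrees
        self.G = build_payoff_table(params, node_cost=0.0).entries
        costs = (
            topology.node_costs
            if topology.node_costs is not None
            else np.full(self.n, params.cost)
        )
        # cost term per node, subtracted from every communicative candidate
        if params.payoff_aggregation == "mean":
            self.inv_deg = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
            self.cost_term = costs.astype(np.float64)
        else:
            self.inv_deg = np.ones(self.n)
            self.cost_term = costs * deg
        self.nbins = 2 * self.d
        self.copy_full_strategy = params.phase_inheritance == "neighbor"

    def attach(self, codes: np.ndarray) -> None:
        self.codes = codes
        self.ncomm = int((codes < self.d).sum())

    def step(self, rng: np.random.Generator) -> None:
        i = int(rng.integers(self.n))
        nb = self.indices[self.indptr[i]: self.indptr[i + 1]]
        if nb.size == 0:
            return
        s_nb = self.codes[nb]
        if self.copy_full_strategy:
            cand = s_nb
        else:
            own_phase = int(self.codes[i]) % self.d
            cand = np.where(s_nb < self.d, own_phase, own_phase + self.d)
        hist = np.bincount(s_nb, minlength=self.nbins)
        pis = (self.G @ hist) * self.inv_deg[i]
        pis[: self.d] -= self.cost_term[i]
        log_w = self.params.delta * pis[cand]
        w = np.exp(log_w - log_w.max())
        new, old = int(cand[_select_from_weights(w, rng)]), int(self.codes[i])
        if new == old:
            return
        self.codes[i] = new
        self.ncomm += int(new < self.d) - int(old < self.d)


def run_simulation(
    params: GameParameters,
    topology: Topology,
    max_iterations: int,
    rng: np.random.Generator | int,
    state: PopulationState | None = None,
    record_trajectory: bool = True,
) -> PopulationState:
    """Run the death-birth process to absorption or the iteration budget.

    Starts from ``state`` if given, else from a fresh single-invader
    configuration drawn with ``rng``.  Stops as soon as the communicative
    fraction hits 0 or 1 (absorbing without mutation); ``absorption_time``
    is the first such iteration, ``None`` if the budget runs out first.
    Fully reproducible for a given seed.  With ``record_trajectory=False``
    only summary statistics are kept; the time average of ``p`` over the
    executed iterations is always available as ``state.time_average_p``.
    """
    if max_iterations < 1:
        raise ValueError(f"max_iterations must be >= 1, got {max_iterations}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if state is None:
        state = initialize_invasion(topology, params.d, rng)
    if state.n != topology.n:
        raise ValueError("state and topology disagree on node count")

    engine = _Engine(topology, params)
    engine.attach(state.codes)
    n = engine.n
    traj = [engine.ncomm / n] if record_trajectory else None
    p_sum = 0.0
    steps = 0
    t = state.iteration
    if not state.absorbed:
        for _ in range(max_iterations):
            engine.step(rng)
            t += 1
            steps += 1
            p = engine.ncomm / n
            p_sum += p
            if record_trajectory:
                traj.append(p)
            if engine.ncomm == 0 or engine.ncomm == n:
                state.absorbed = True
                state.absorption_time = t
                break
    state.iteration = t
    if record_trajectory:
        state.trajectory = traj
    else:
        state.trajectory = [engine.ncomm / n]
    state.time_average_p = p_sum / steps if steps else state.p
    return state


def export_trajectory(state: PopulationState, path, decimate: int = 1) -> None:
    """Write the recorded trajectory as CSV (iteration, p), optionally
    keeping every ``decimate``-th iteration (the final entry is always kept)."""
    import csv

    if decimate < 1:
        raise ValueError("decimate must be >= 1")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "p"])
        last = len(state.trajectory) - 1
        for t, p in enumerate(state.trajectory):
            if t % decimate == 0 or t == last:
                writer.writerow([t, format(p, ".10g")])
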