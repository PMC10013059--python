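"""Exact ground truth for the stochastic engine on tiny systems.

In the invasion setting each node carries one of two strategies per site —
communicative or silent at the site's phase — so the death-birth process
restricted to a fixed phase field is an absorbing Markov chain over the
``2^n`` flag assignments, with exactly two absorbing states (all
communicative, all silent).  For ``n`` up to about ten the transition
matrix can be enumerated exactly and the fixation probability obtained
from the absorbing-chain linear system.  The enumeration calls the same
payoff and fitness-profile code the production dynamics uses, so a
Monte-Carlo/exact match validates the stochastic sampling, not just the
formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    PopulationState,
    fitness_profile,
    initialize_invasion,
    invader_phase_index,
    run_simulation,
)
from .game import GameParameters, Strategy
from .topology import Topology

__all__ = [
    "TwoStrategyChain",
    "build_transition_operator",
    "exact_fixation_probability",
    "mean_single_invader_fixation",
    "monte_carlo_fixation",
    "single_invader_state",
]

MAX_NODES = 12


def single_invader_state(
    topology: Topology, params: GameParameters, invader_node: int = 0
) -> PopulationState:
    """Deterministic single-invader configuration: silent residents at phase
    1 everywhere, one communicator at the maximally distant phase placed at
    ``invader_node``."""
    d = params.d
    codes = np.full(topology.n, Strategy("N", 1).code(d), dtype=np.int64)
    codes[invader_node] = Strategy("C", invader_phase_index(d)).code(d)
    return PopulationState(codes=codes, d=d)


@dataclass
class TwoStrategyChain:
    """Exact death-birth chain over flag assignments on a small topology.

    The phase field (one phase per site) is frozen at the initial state's
    phases — matching the default dynamics, where replacements keep the
    site's phase.  States are bitmasks over the nodes: bit ``i`` set means
    node ``i`` is communicative.  Under
    ``params.phase_inheritance='neighbor'`` the two per-site options are
    instead the initial state's global invader/resident strategy pair, the
    only strategies pure imitation can ever produce.
    """

    topology: Topology
    params: GameParameters
    initial_state: PopulationState | None = None
    transition: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = self.topology.n
        if n > MAX_NODES:
            raise ValueError(
                f"chain enumeration limited to n <= {MAX_NODES}, got n={n}"
            )
        if self.initial_state is None:
            self.initial_state = single_invader_state(self.topology, self.params)
        d = self.params.d
        codes = self.initial_state.codes
        if self.params.phase_inheritance == "neighbor":
            comm = codes[codes < d]
            silent = codes[codes >= d]
            inv = int(comm[0]) if comm.size else Strategy("C", invader_phase_index(d)).code(d)
            res = int(silent[0]) if silent.size else Strategy("N", 1).code(d)
            self._code_if_comm = np.full(n, inv, dtype=np.int64)
            self._code_if_silent = np.full(n, res, dtype=np.int64)
        else:
            phases = codes % d
            self._code_if_comm = phases.astype(np.int64)
            self._code_if_silent = phases.astype(np.int64) + d

    @property
    def n(self) -> int:
        return self.topology.n

    @property
    def n_states(self) -> int:
        return 1 << self.n

    def bits(self, mask: int) -> np.ndarray:
        return (mask >> np.arange(self.n)) & 1

    def state_codes(self, mask: int) -> np.ndarray:
        return np.where(self.bits(mask) == 1, self._code_if_comm, self._code_if_silent)

    def mask_of(self, state: PopulationState) -> int:
        flags = state.codes < self.params.d
        return int(np.sum(flags.astype(np.int64) << np.arange(self.n)))

    @property
    def all_communicative(self) -> int:
        return self.n_states - 1

    @property
    def all_silent(self) -> int:
        return 0


def build_transition_operator(chain: TwoStrategyChain) -> np.ndarray:
    """Dense row-stochastic transition matrix of the restricted chain.

    For each state, the death node is uniform over the ``n`` nodes and the
    replacement is drawn from the exact fitness profile of the
    pre-replacement configuration (the same code path the simulations
    use); a neighborless node's death leaves the state unchanged.
    Homogeneous states are absorbing by construction.
    """
    n, n_states = chain.n, chain.n_states
    params, topology = chain.params, chain.topology
    T = np.zeros((n_states, n_states))
    for mask in range(n_states):
        state = PopulationState(codes=chain.state_codes(mask), d=params.d)
        bits = chain.bits(mask)
        for i in range(n):
            nb = topology.neighbors(i)
            if nb.size == 0:
                T[mask, mask] += 1.0 / n
                continue
            idx, probs = fitness_profile(state, params, topology, i)
            # the candidate a neighbor proposes carries that neighbor's flag
            p_comm = float(probs[bits[idx] == 1].sum())
            T[mask, mask | (1 << i)] += p_comm / n
            T[mask, mask & ~(1 << i)] += (1.0 - p_comm) / n
    return T


def exact_fixation_probability(chain: TwoStrategyChain, start_mask: int) -> float:
    """Probability of absorbing in the all-communicative state from
    ``start_mask``, via the absorbing-chain linear system ``h = T h`` with
    ``h`` pinned to 1 (all communicative) and 0 (all silent)."""
    if not 0 <= start_mask < chain.n_states:
        raise ValueError(f"start state {start_mask} out of range")
    if start_mask == chain.all_communicative:
        return 1.0
    if start_mask == chain.all_silent:
        return 0.0
    if chain.transition is None:
        chain.transition = build_transition_operator(chain)
    T = chain.transition
    absorbing = {chain.all_communicative, chain.all_silent}
    transient = [s for s in range(chain.n_states) if s not in absorbing]
    Q = T[np.ix_(transient, transient)]
    b = T[transient, chain.all_communicative]
    h = np.linalg.solve(np.eye(len(transient)) - Q, b)
    return float(h[transient.index(start_mask)])


def mean_single_invader_fixation(chain: TwoStrategyChain) -> float:
    """Fixation probability averaged over the ``n`` one-communicator states
    of the chain's fixed phase field.  On vertex-transitive topologies with
    a uniform phase field this equals the fixation probability of a
    uniformly placed invader."""
    return float(
        np.mean([exact_fixation_probability(chain, 1 << i) for i in range(chain.n)])
    )


def monte_carlo_fixation(
    params: GameParameters,
    topology: Topology,
    trials: int,
    rng: np.random.Generator | int,
    initial_state: PopulationState | None = None,
    max_iterations: int = 500_000,
) -> tuple[float, float]:
    """Invader fixation frequency over repeated runs to absorption.

    Each trial restarts from a copy of ``initial_state`` (or, if omitted,
    from a fresh uniformly placed single invader) and scores 1 if the
    communicative flag fixed.  Returns the frequency and its binomial
    standard error.  Raises if a trial fails to absorb within
    ``max_iterations``.
    """
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    wins = 0
    for _ in range(trials):
        if initial_state is None:
            start = initialize_invasion(topology, params.d, rng)
        else:
            start = PopulationState(codes=initial_state.codes.copy(), d=params.d)
        final = run_simulation(
            params, topology, max_iterations, rng, state=start,
            record_trajectory=False,
        )
        if not final.absorbed:
            raise RuntimeError(
                f"trial did not absorb within {max_iterations} iterations"
            )
        wins += int(final.p == 1.0)
    p_hat = wins / trials
    stderr = float(np.sqrt(p_hat * (1.0 - p_hat) / trials))
    return p_hat, stderr


def export_fixation_table(chain: TwoStrategyChain, path) -> None:
    """CSV of exact fixation probability for every state of the chain."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["state_mask", "n_communicative", "fixation_probability"])
        for mask in range(chain.n_states):
            writer.writerow(
                [mask, bin(mask).count("1"),
                 format(exact_fixation_probability(chain, mask), ".12g")]
            )
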