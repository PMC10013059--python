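"""Payoff structure of the oscillator communication game.

Agents are oscillators with identical periods, each carrying a strategy
``(flag, phase_index)``: the flag says whether the oscillator communicates
with its neighbors (``C``) or not (``N``), and the phase index is one of
``d`` evenly spaced positions on the oscillation cycle.  Interactions are
pairwise: a communicator pays a cost ``c`` and receives a benefit that
decays linearly with the cyclic distance between the two phases — ``B`` when
the partner communicates, the smaller ``beta`` when it does not.
Non-communicators pay nothing and free-ride on ``beta`` against
communicators; two non-communicators exchange nothing.

The resulting ``2d x 2d`` payoff matrix, indexed by the strategy list
``(C, phi_1) ... (C, phi_d), (N, phi_1) ... (N, phi_d)``, has four ``d x d``
blocks and is the single object the death-birth dynamics consults.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "Strategy",
    "GameParameters",
    "PayoffTable",
    "cyclic_phase_index_distance",
    "benefit_B",
    "benefit_beta",
    "build_payoff_table",
    "payoff",
    "classify_game",
]

COMMUNICATIVE = "C"
NON_COMMUNICATIVE = "N"

#: Game-region labels returned by :func:`classify_game`.
GAME_REGIONS = ("mutualism", "snowdrift", "coordination", "prisoners_dilemma", "boundary")


@dataclass(frozen=True)
class Strategy:
    """A full agent description: communication flag plus phase index.

    Parameters
    ----------
    flag
        ``"C"`` for a communicative oscillator, ``"N"`` for a silent one.
    phase_index
        1-based position on the cycle of ``d`` evenly spaced phases.  The
        upper bound depends on ``d`` and is validated where a table is
        consulted.
    """

    flag: str
    phase_index: int

    def __post_init__(self) -> None:
        if self.flag not in (COMMUNICATIVE, NON_COMMUNICATIVE):
            raise ValueError(f"flag must be 'C' or 'N', got {self.flag!r}")
        if self.phase_index < 1:
            raise ValueError(f"phase_index must be >= 1, got {self.phase_index}")

    @property
    def communicates(self) -> bool:
        return self.flag == COMMUNICATIVE

    def code(self, d: int) -> int:
        """0-based index of this strategy in the canonical strategy list."""
        if self.phase_index > d:
            raise ValueError(f"phase_index {self.phase_index} out of range for d={d}")
        offset = 0 if self.communicates else d
        return offset + self.phase_index - 1

    @staticmethod
    def from_code(code: int, d: int) -> "Strategy":
        if not 0 <= code < 2 * d:
            raise ValueError(f"strategy code {code} out of range for d={d}")
        flag = COMMUNICATIVE if code < d else NON_COMMUNICATIVE
        return Strategy(flag, code % d + 1)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.flag},phi{self.phase_index})"


@dataclass(frozen=True)
class GameParameters:
    """Cost/benefit parameters defining the payoff table and selection.

    Attributes
    ----------
    b0 : float
        Benefit intercept ``B(0)`` for interactions with a communicator.
    beta0 : float
        Benefit intercept ``beta(0)`` for interactions with a
        non-communicator; must satisfy ``b0 >= beta0 >= 0`` so that
        ``B(k) >= beta(k)`` for every cyclic distance ``k``.
    cost : float
        Base communication cost ``c`` (default 10).
    cost_mode : {"uniform", "degree_adjusted"}
        Uniform assigns ``c`` to every node; degree-adjusted scales it by
        relative degree, ``c(i) = c * N(i) / mu``, keeping the mean cost at
        ``c``.
    d : int
        Number of evenly spaced phases (>= 2).
    delta : float
        Selection strength in the exponential fitness ``f = exp(delta*pi)``.
    payoff_aggregation : {"sum", "mean"}
        Whether the expected payoff is the sum of per-neighbor payoffs (the
        default, matching the displayed definition) or their mean.
    phase_inheritance : {"node", "neighbor"}
        What the death-birth replacement inherits besides the chosen
        neighbor's communication flag.  ``"node"`` (default): the new
        oscillator keeps the phase of the site it occupies — the phase is a
        physical configuration of the oscillator at that location, and the
        evolving trait is whether it communicates.  ``"neighbor"``: the
        full (flag, phase) strategy of the chosen neighbor is copied.
    """

    b0: float
    beta0: float
    cost: float = 10.0
    cost_mode: str = "uniform"
    d: int = 10
    delta: float = 1.0
    payoff_aggregation: str = "sum"
    phase_inheritance: str = "node"

    def __post_init__(self) -> None:
        if not (self.b0 >= self.beta0 >= 0):
            raise ValueError(
                f"need b0 >= beta0 >= 0, got b0={self.b0}, beta0={self.beta0}"
            )
        if self.cost < 0:
            raise ValueError(f"cost must be >= 0, got {self.cost}")
        if self.cost_mode not in ("uniform", "degree_adjusted"):
            raise ValueError(f"unknown cost_mode {self.cost_mode!r}")
        if self.d < 2:
            raise ValueError(f"d must be >= 2, got {self.d}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if self.payoff_aggregation not in ("sum", "mean"):
            raise ValueError(f"unknown payoff_aggregation {self.payoff_aggregation!r}")
        if self.phase_inheritance not in ("node", "neighbor"):
            raise ValueError(f"unknown phase_inheritance {self.phase_inheritance!r}")

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "b0": self.b0,
            "beta0": self.beta0,
            "cost": self.cost,
            "cost_mode": self.cost_mode,
            "d": self.d,
            "delta": self.delta,
            "payoff_aggregation": self.payoff_aggregation,
            "phase_inheritance": self.phase_inheritance,
        }

    @staticmethod
    def from_dict(data: dict) -> "GameParameters":
        return GameParameters(**data)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @staticmethod
    def from_json(text: str) -> "GameParameters":
        return GameParameters.from_dict(json.loads(text))

    def with_(self, **kwargs) -> "GameParameters":
        return replace(self, **kwargs)


def cyclic_phase_index_distance(q: int, r: int, d: int) -> int:
    """Minimal number of steps between phase indices ``q`` and ``r`` on the d-cycle.

    Returns ``|q - r|`` when that is at most ``d // 2`` and ``d - |q - r|``
    otherwise, so the result lies in ``{0, ..., d // 2}`` and is symmetric.
    """
    if d < 2:
        raise ValueError(f"d must be >= 2, got {d}")
    if not (1 <= q <= d and 1 <= r <= d):
        raise ValueError(f"phase indices must lie in 1..{d}, got q={q}, r={r}")
    diff = abs(q - r)
    return diff if diff <= d // 2 else d - diff


def benefit_B(k: int, params: GameParameters) -> float:
    """Communicator benefit ``B(k) = B(0) * (1 - k/d)`` at cyclic distance ``k``."""
    _check_k(k, params.d)
    return params.b0 * (1.0 - k / params.d)


def benefit_beta(k: int, params: GameParameters) -> float:
    """Non-communicator benefit ``beta(k) = beta(0) * (1 - k/d)``."""
    _check_k(k, params.d)
    return params.beta0 * (1.0 - k / params.d)


def _check_k(k: int, d: int) -> None:
    if not 0 <= k <= d // 2:
        raise ValueError(f"cyclic distance k must lie in 0..{d // 2}, got {k}")


@dataclass(frozen=True)
class PayoffTable:
    """The ``2d x 2d`` payoff matrix with its generating parameters.

    ``entries[i, j]`` is the payoff *to the row player* when the row
    strategy meets the column strategy; rows/columns follow the canonical
    strategy list (all ``C`` phases first, then all ``N`` phases).
    ``node_cost`` is the communication cost baked into the cost-bearing
    blocks — the global ``c`` in uniform mode, or the focal node's ``c(i)``
    in degree-adjusted mode.
    """

    entries: np.ndarray = field(repr=False)
    params: GameParameters
    node_cost: float

    @property
    def d(self) -> int:
        return self.params.d

    @property
    def strategies(self) -> list[Strategy]:
        d = self.d
        return [Strategy.from_code(i, d) for i in range(2 * d)]

    def entry(self, s_row: Strategy, s_col: Strategy) -> float:
        return float(self.entries[s_row.code(self.d), s_col.code(self.d)])

    def to_csv(self, path: str | Path) -> None:
        """Write the table with strategy labels on both axes."""
        labels = [str(s) for s in self.strategies]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["strategy", *labels])
            for label, row in zip(labels, self.entries):
                writer.writerow([label, *(format(v, ".10g") for v in row)])


def build_payoff_table(params: GameParameters, node_cost: float | None = None) -> PayoffTable:
    """Assemble the full payoff matrix for one focal node.

    The four ``d x d`` blocks are, reading row-flag x column-flag:

    * ``C x C``: ``-c + B(k)`` — pay the cost, reap the full benefit;
    * ``C x N``: ``-c + beta(k)`` — pay the cost, reap the reduced benefit;
    * ``N x C``: ``beta(k)`` — free-ride on the communicator;
    * ``N x N``: ``0`` — silent pairs exchange nothing.

    ``k`` is the cyclic distance between the two phase indices, so every
    entry depends only on the flags and ``k``, making the table invariant
    under simultaneous rotation of both phases.
    """
    if node_cost is None:
        node_cost = params.cost
    if node_cost < 0:
        raise ValueError(f"node_cost must be >= 0, got {node_cost}")
    d = params.d
    # k[q, r] for 1-based phases q, r laid out on a 0-based grid
    idx = np.arange(d)
    diff = np.abs(idx[:, None] - idx[None, :])
    k = np.minimum(diff, d - diff)
    bee = params.b0 * (1.0 - k / d)
    beta = params.beta0 * (1.0 - k / d)
    entries = np.zeros((2 * d, 2 * d))
    entries[:d, :d] = -node_cost + bee
    entries[:d, d:] = -node_cost + beta
    entries[d:, :d] = beta
    # lower-right block stays identically zero
    return PayoffTable(entries=entries, params=params, node_cost=float(node_cost))


def payoff(table: PayoffTable, s_row: Strategy, s_col: Strategy) -> float:
    """Payoff to ``s_row`` when meeting ``s_col`` under ``table``."""
    return table.entry(s_row, s_col)


def classify_game(params: GameParameters) -> str:
    """Classify the reduced same-phase 2x2 game between ``C`` and ``N``.

    At equal phase the payoffs are R = B(0) - c (mutual communication),
    S = beta(0) - c (communicate against a silent partner), T = beta(0)
    (free-ride), P = 0.  The signs of ``R - T = B(0) - beta(0) - c`` and
    ``S - P = beta(0) - c`` select the region:

    * both positive → mutualism (harmony): communication dominates;
    * ``R - T < 0 < S - P`` → snowdrift: stable mixed equilibrium;
    * ``S - P < 0 < R - T`` → coordination: bistable;
    * both negative → prisoner's dilemma: defection dominates;
    * either difference exactly zero → ``"boundary"``.
    """
    r_minus_t = params.b0 - params.beta0 - params.cost
    s_minus_p = params.beta0 - params.cost
    if r_minus_t == 0 or s_minus_p == 0:
        return "boundary"
    if r_minus_t > 0 and s_minus_p > 0:
        return "mutualism"
    if r_minus_t < 0 and s_minus_p > 0:
        return "snowdrift"
    if r_minus_t > 0 and s_minus_p < 0:
        return "coordination"
    return "prisoners_dilemma"


def classification_table(
    b0_values: Iterable[float], cost: float = 10.0, d: int = 10
) -> "list[tuple[float, float, str]]":
    """Region label for every (b0, beta0) pair with beta0 in 1..b0 (integers)."""
    rows = []
    for b0 in b0_values:
        for beta0 in range(1, int(b0) + 1):
            label = classify_game(GameParameters(b0=b0, beta0=beta0, cost=cost, d=d))
            rows.append((float(b0), float(beta0), label))
    return rows
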