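"""Parameter sweeps over benefit intercepts and result aggregation.

A sweep runs the single-invader death-birth simulation for every benefit
pair ``(B(0), beta(0))`` on a grid of integer intercepts (by default
``B(0)`` in 1..40 and ``beta(0)`` in 1..B(0), i.e. 820 pairs), with a fixed
number of trials per pair, and aggregates the per-trial outcomes into the
two headline summaries: the mean final communicative percentage and the
mean convergence time, where non-converged trials contribute the iteration
budget as a sentinel.  Trial seeds are derived deterministically from the
master seed and the pair/trial labels, so any subset of pairs can be
recomputed independently and byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .game import GameParameters, classify_game
from .topology import Topology, assign_costs, make_topology

__all__ = [
    "SweepConfig",
    "SweepResult",
    "run_sweep",
    "run_trials",
    "convergence_time_summary",
    "region_annotation",
    "export_results",
]

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = [
    "b0", "beta0", "trial", "seed", "final_p", "time_average_p",
    "convergence_iteration", "absorbed",
]


@dataclass(frozen=True)
class SweepConfig:
    """Full description of a sweep; every field mirrors a CLI flag.

    Defaults reproduce the headline protocol: a 40x40 grid (1,600
    oscillators), d=10 phases, selection strength delta=1, base cost 10,
    50,000 iterations and 20 trials per pair, benefit intercepts
    ``B(0)`` in 1..40 with ``beta(0)`` in 1..B(0).
    """

    topology: str = "nn8"
    width: int = 40
    height: int = 40
    gamma: float = 10.0
    b0_values: tuple[int, ...] = tuple(range(1, 41))
    beta0_values: tuple[int, ...] | None = None  # None => 1..B0 per pair
    cost: float = 10.0
    cost_mode: str = "uniform"
    d: int = 10
    delta: float = 1.0
    max_iterations: int = 50_000
    trials: int = 20
    seed: int = 0
    payoff_aggregation: str = "sum"

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        # explicit beta0 values above every b0 would leave an empty sweep
        if not any(True for _ in self.pairs()):
            raise ValueError("sweep contains no valid (b0, beta0) pairs")

    def pairs(self) -> Iterator[tuple[int, int]]:
        """The swept (B(0), beta(0)) pairs, beta0 <= b0 always."""
        for b0 in self.b0_values:
            betas = self.beta0_values if self.beta0_values is not None \
                else range(1, int(b0) + 1)
            for beta0 in betas:
                if self.beta0_values is None or beta0 <= b0:
                    yield int(b0), int(beta0)

    def game_parameters(self, b0: int, beta0: int) -> GameParameters:
        return GameParameters(
            b0=b0, beta0=beta0, cost=self.cost, cost_mode=self.cost_mode,
            d=self.d, delta=self.delta, payoff_aggregation=self.payoff_aggregation,
        )

    def trial_seed_sequence(self, b0: int, beta0: int, trial: int) -> np.random.SeedSequence:
        """Deterministic per-trial entropy from (master seed, pair, trial)."""
        return np.random.SeedSequence((self.seed, b0, beta0, trial))

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["b0_values"] = list(self.b0_values)
        if self.beta0_values is not None:
            out["beta0_values"] = list(self.beta0_values)
        return out

    @staticmethod
    def from_dict(data: dict) -> "SweepConfig":
        data = dict(data)
        if "b0_values" in data:
            data["b0_values"] = tuple(data["b0_values"])
        if data.get("beta0_values") is not None:
            data["beta0_values"] = tuple(data["beta0_values"])
        return SweepConfig(**data)


@dataclass
class SweepResult:
    """Per-trial records plus per-pair aggregates of one sweep."""

    config: SweepConfig
    trials: pd.DataFrame = field(repr=False)
    pairs: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.pairs is None:
            self.pairs = aggregate_pairs(self.trials, self.config)


def _build_fixed_topology(config: SweepConfig) -> Topology | None:
    if config.topology == "probabilistic_spatial":
        return None  # fresh instance per trial
    topo = make_topology(config.topology, config.width, config.height)
    return assign_costs(topo, config.cost, config.cost_mode)


def run_trials(
    config: SweepConfig,
    b0: int,
    beta0: int,
    fixed_topology: Topology | None = None,
) -> list[dict]:
    """All trials for one benefit pair; returns per-trial record dicts."""
    from .dynamics import run_simulation

    params = config.game_parameters(b0, beta0)
    records = []
    for trial in range(config.trials):
        ss = config.trial_seed_sequence(b0, beta0, trial)
        topo_stream, dyn_stream = ss.spawn(2)
        if fixed_topology is not None:
            topo = fixed_topology
        else:
            topo = make_topology(
                config.topology, config.width, config.height, config.gamma,
                rng=np.random.default_rng(topo_stream),
            )
            topo = assign_costs(topo, config.cost, config.cost_mode)
        final = run_simulation(
            params, topo, config.max_iterations,
            np.random.default_rng(dyn_stream), record_trajectory=False,
        )
        records.append({
            "b0": b0,
            "beta0": beta0,
            "trial": trial,
            "seed": int(ss.generate_state(1)[0]),
            "final_p": final.p,
            "time_average_p": final.time_average_p,
            "convergence_iteration": (
                final.absorption_time if final.absorbed else config.max_iterations
            ),
            "absorbed": final.absorbed,
        })
    return records


def aggregate_pairs(trials: pd.DataFrame, config: SweepConfig) -> pd.DataFrame:
    """Per-pair means; non-converged trials carry the sentinel budget in
    ``convergence_iteration`` already, so a plain mean implements the
    sentinel convention."""
    grouped = trials.groupby(["b0", "beta0"], as_index=False).agg(
        mean_final_p=("final_p", "mean"),
        mean_convergence_time=("convergence_iteration", "mean"),
        n_trials=("trial", "count"),
        n_nonconverged=("absorbed", lambda s: int((~s.astype(bool)).sum())),
    )
    grouped["region"] = [
        classify_game(config.game_parameters(int(r.b0), int(r.beta0)))
        for r in grouped.itertuples()
    ]
    return grouped


def run_sweep(config: SweepConfig, progress: bool = False) -> SweepResult:
    """Run every pair x trial simulation of ``config`` and aggregate.

    Fixed topologies (all-to-all, nn4, nn8) are built once; the
    probabilistic spatial topology is regenerated independently per trial.
    Reproducible from the master seed alone.
    """
    fixed = _build_fixed_topology(config)
    all_pairs = list(config.pairs())
    if not all_pairs:
        raise ValueError("sweep has no (b0, beta0) pairs")
    records: list[dict] = []
    t0 = time.perf_counter()
    for idx, (b0, beta0) in enumerate(all_pairs):
        records.extend(run_trials(config, b0, beta0, fixed))
        if progress and (idx + 1) % max(1, len(all_pairs) // 20) == 0:
            logger.info(
                "sweep %d/%d pairs done (%.1fs)",
                idx + 1, len(all_pairs), time.perf_counter() - t0,
            )
    trials = pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS)
    return SweepResult(config=config, trials=trials)


def convergence_time_summary(result: SweepResult) -> pd.DataFrame:
    """Mean convergence time arranged on the (beta0 rows, b0 columns) grid;
    pairs absent from the sweep appear as NaN gaps, never as zeros."""
    return result.pairs.pivot(
        index="beta0", columns="b0", values="mean_convergence_time"
    )


def region_annotation(result: SweepResult, cost: float | None = None) -> pd.DataFrame:
    """Mean final communicative fraction summarized by game region.

    The expected invasion outcome is ``C`` wherever ``beta0 > cost`` (with
    ``b0 >= beta0``), ``N`` in the prisoner's-dilemma and coordination
    regions, and undefined on boundaries (flagged, excluded from
    region-level expectations).
    """
    cost = result.config.cost if cost is None else cost
    pairs = result.pairs.copy()
    pairs["expected_outcome"] = [
        None if row.region == "boundary" else ("C" if row.beta0 > cost else "N")
        for row in pairs.itertuples()
    ]
    summary = pairs.groupby("region", as_index=False).agg(
        n_pairs=("region", "count"),
        mean_final_p=("mean_final_p", "mean"),
        mean_convergence_time=("mean_convergence_time", "mean"),
    )
    summary.attrs["pair_annotations"] = pairs
    return summary


def export_results(
    result: SweepResult, destination: str | Path, heatmaps: bool = False
) -> dict[str, Path]:
    """Write per-trial CSV, per-pair summary CSV, and a JSON run manifest.

    With ``heatmaps=True`` also renders the two summary grids (mean final
    communicative fraction and mean convergence time) as PNG images;
    rendering requires matplotlib and is cosmetic, not part of the data
    surface.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": dest / "trials.csv",
        "summary": dest / "summary.csv",
        "manifest": dest / "manifest.json",
    }
    result.trials.to_csv(paths["trials"], index=False)
    result.pairs.to_csv(paths["summary"], index=False)
    try:
        from importlib.metadata import version

        pkg_version = version("syncgame")
    except Exception:  # pragma: no cover
        pkg_version = "unknown"
    manifest = {
        "config": result.config.to_dict(),
        "master_seed": result.config.seed,
        "n_pairs": int(len(result.pairs)),
        "n_trials_total": int(len(result.trials)),
        "package_version": pkg_version,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    if heatmaps:
        paths.update(_render_heatmaps(result, dest))
    return paths


def _render_heatmaps(result: SweepResult, dest: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = {}
    for name, column, label in [
        ("final_p", "mean_final_p", "mean final communicative fraction"),
        ("convergence", "mean_convergence_time", "mean convergence time (iterations)"),
    ]:
        grid = result.pairs.pivot(index="beta0", columns="b0", values=column)
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(grid.to_numpy(), origin="lower", aspect="auto",
                       extent=[grid.columns.min(), grid.columns.max(),
                               grid.index.min(), grid.index.max()])
        ax.set_xlabel("B(0)")
        ax.set_ylabel("beta(0)")
        fig.colorbar(im, ax=ax, label=label)
        path = dest / f"heatmap_{name}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        out[f"heatmap_{name}"] = path
    return out
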