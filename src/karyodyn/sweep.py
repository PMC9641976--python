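"""Sweep of the (Y cost, Y^S cost) plane.

For each grid cell (y, s) a set of independent stochastic replicates is
run and summarized by the mean Y^S share averaged over the first 100
generations and by the Y^S persistence probability — the fraction of
replicates that still carry at least one Y^S chromosome at the end of
the averaging window.  Replicate seeds derive deterministically from the
cell coordinates, so cell results do not depend on traversal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import FitnessParams
from .wright_fisher import SimConfig, Trajectory, run

__all__ = [
    "SweepGrid",
    "SweepResult",
    "average_ys_frequency",
    "ys_present_at",
    "persistence_probability",
    "run_sweep",
    "default_grid_values",
]


def default_grid_values(step: float = 0.05) -> List[float]:
    """Grid axis 0, step, ..., 1 (costs; negative values are allowed too)."""
    n = int(round(1.0 / step))
    return [round(i * step, 10) for i in range(n + 1)]


@dataclass(frozen=True)
class SweepGrid:
    """A rectangular grid over (full-Y cost ``y``, Y^S cost ``s``)."""

    y_values: Sequence[float] = field(default_factory=default_grid_values)
    s_values: Sequence[float] = field(default_factory=default_grid_values)
    replicates: int = 100
    base_config: SimConfig = field(default_factory=lambda: SimConfig(generations=100))
    window: int = 100
    post_extinction: str = "carry_last"  # or "undefined"

    def __post_init__(self) -> None:
        if not self.y_values or not self.s_values:
            raise ValueError("sweep grid must be non-empty")
        for v in list(self.y_values) + list(self.s_values):
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"cost values must lie in [-1, 1], got {v}")
        if self.replicates < 1:
            raise ValueError("replicates must be positive")


def _window_shares(
    trajectory: Trajectory, window: int, post_extinction: str
) -> np.ndarray:
    """Y^S shares over generations 1..window, padded past extinction.

    A population-extinct run ends early; by default its last defined
    share is carried forward over the missing generations
    (``post_extinction="undefined"`` pads with NaN instead).
    """
    shares = trajectory.ys_shares[1 : window + 1]
    missing = window - len(shares)
    if missing > 0:
        if post_extinction == "carry_last":
            pad_value = shares[-1] if len(shares) else trajectory.ys_shares[0]
        elif post_extinction == "undefined":
            pad_value = np.nan
        else:
            raise ValueError(f"unknown post_extinction policy: {post_extinction!r}")
        shares = np.concatenate([shares, np.full(missing, pad_value)])
    return shares


def average_ys_frequency(
    trajectory: Trajectory, window: int = 100, post_extinction: str = "carry_last"
) -> float:
    """Mean Y^S share over generations 1..window of one trajectory."""
    shares = _window_shares(trajectory, window, post_extinction)
    if np.all(np.isnan(shares)):
        return float("nan")
    return float(np.nanmean(shares))


def ys_present_at(trajectory: Trajectory, generation: int) -> bool:
    """Whether any Y^S chromosome exists at the given generation.

    A run already population-extinct by then counts as not persistent.
    """
    if generation > trajectory.n_generations:
        return False
    return trajectory.ys_shares[generation] > 0


def persistence_probability(
    trajectories: Sequence[Trajectory], generation: int = 100
) -> float:
    """Fraction of replicates retaining Y^S at the end of the window."""
    if not trajectories:
        raise ValueError("persistence_probability needs at least one replicate")
    return sum(ys_present_at(t, generation) for t in trajectories) / len(trajectories)


@dataclass
class SweepResult:
    """Per-cell summaries, as a tidy table ordered by (y, s)."""

    table: pd.DataFrame

    def heatmap_matrix(self, value: str = "mean_avg_ys_freq") -> pd.DataFrame:
        return self.table.pivot(index="y_cost", columns="s_cost", values=value)


def _cell_rng(root_seed: int, iy: int, js: int, rep: int) -> np.random.Generator:
    # Seed depends only on (cell coordinates, replicate), never on traversal order.
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), iy, js, rep]))


def run_cell(
    grid: SweepGrid, iy: int, js: int, return_trajectories: bool = False
):
    """All replicates of one grid cell; returns the summary row (and
    optionally the trajectories)."""
    y = grid.y_values[iy]
    s = grid.s_values[js]
    base = grid.base_config
    params = replace(base.params, y=y, s=s)
    config = replace(base, params=params, generations=max(base.generations, grid.window))
    trajectories = []
    for rep in range(grid.replicates):
        rng = _cell_rng(base.seed, iy, js, rep)
        trajectories.append(run(config, rng))
    avgs = np.array(
        [
            average_ys_frequency(t, grid.window, grid.post_extinction)
            for t in trajectories
        ]
    )
    row = {
        "y_cost": y,
        "s_cost": s,
        "mean_avg_ys_freq": float(np.nanmean(avgs)) if not np.all(np.isnan(avgs)) else float("nan"),
        "persistence_prob": persistence_probability(trajectories, grid.window),
        "extinction_rate": sum(t.extinct for t in trajectories) / len(trajectories),
        "replicates": grid.replicates,
        "seed": base.seed,
    }
    if return_trajectories:
        return row, trajectories
    return row


def run_sweep(grid: SweepGrid, progress: bool = False) -> SweepResult:
    """Run every cell of the grid and collect the summary table."""
    cells = [(iy, js) for iy in range(len(grid.y_values)) for js in range(len(grid.s_values))]
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm

            cells = tqdm(cells, desc="sweep")
        except ImportError:
            pass
    rows = [run_cell(grid, iy, js) for iy, js in cells]
    table = pd.DataFrame(rows).sort_values(["y_cost", "s_cost"]).reset_index(drop=True)
    return SweepResult(table)


def frequency_by_cost_difference(result: SweepResult) -> pd.DataFrame:
    """Mean Y^S frequency grouped by the female cost difference y − s.

    The fitness-difference view of the sweep: the larger the advantage of
    the truncated chromosome in females, the higher its average share.
    """
    t = result.table.copy()
    t["cost_difference"] = (t["y_cost"] - t["s_cost"]).round(10)
    return (
        t.groupby("cost_difference")[["mean_avg_ys_freq", "persistence_prob"]]
        .mean()
        .reset_index()
    )
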