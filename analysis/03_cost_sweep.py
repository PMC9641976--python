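"""Sweep the (Y cost, Y^S cost) plane and summarize Y^S maintenance.

Runs an 11 x 11 grid over y, s in {0, 0.1, ..., 1} at N = 100 with 40
replicates per cell and a 100-generation window (a coarser, lighter
version of the full 21 x 21 / 100-replicate grid; pass --fine for that
one).  Per cell: mean Y^S share over generations 1-100 and persistence
probability (fraction of replicates still carrying Y^S at generation
100).  Writes results/cost_sweep.tsv, the cost-difference summary
results/cost_sweep_by_difference.tsv, and a heatmap if matplotlib is
available.

The headline pattern: cells with y - s > 0.5 keep Y^S with probability
above 90%, while the diagonal y = s loses it almost always.
"""

import argparse
from pathlib import Path

from karyodyn import SimConfig, SweepGrid, run_sweep
from karyodyn.sweep import default_grid_values, frequency_by_cost_difference

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--fine", action="store_true",
                        help="full 21x21 grid at 100 replicates per cell")
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    step = 0.05 if args.fine else 0.1
    replicates = 100 if args.fine else 40
    values = default_grid_values(step)
    grid = SweepGrid(
        y_values=values,
        s_values=values,
        replicates=replicates,
        base_config=SimConfig(population_size=100, generations=100, seed=args.seed),
        window=100,
    )
    result = run_sweep(grid, progress=True)
    result.table.to_csv(RESULTS / "cost_sweep.tsv", sep="\t", index=False)
    by_diff = frequency_by_cost_difference(result)
    by_diff.to_csv(RESULTS / "cost_sweep_by_difference.tsv", sep="\t", index=False)

    t = result.table
    large_diff = t[t.y_cost - t.s_cost > 0.5]
    diagonal = t[t.y_cost == t.s_cost]
    print(f"grid: {len(values)}x{len(values)}, {replicates} replicates/cell")
    print(f"cells with y - s > 0.5: min persistence "
          f"{large_diff.persistence_prob.min():.2f}, "
          f"mean Y^S share {large_diff.mean_avg_ys_freq.mean():.3f}")
    print(f"diagonal y = s: mean persistence {diagonal.persistence_prob.mean():.2f}, "
          f"mean Y^S share {diagonal.mean_avg_ys_freq.mean():.3f}")
    print(f"wrote {RESULTS / 'cost_sweep.tsv'} and cost_sweep_by_difference.tsv")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        matrix = result.heatmap_matrix()
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(
            matrix.to_numpy(), origin="lower", aspect="auto", vmin=0, vmax=1,
            extent=(min(values), max(values), min(values), max(values)),
            cmap="viridis",
        )
        ax.set_xlabel("Y^S cost (s)")
        ax.set_ylabel("Y cost (y)")
        fig.colorbar(im, ax=ax, label="mean Y^S share, generations 1-100")
        fig.savefig(RESULTS / "cost_sweep_heatmap.png", dpi=150, bbox_inches="tight")
        print(f"wrote {RESULTS / 'cost_sweep_heatmap.png'}")
    except ImportError:
        pass


if __name__ == "__main__":
    main()
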