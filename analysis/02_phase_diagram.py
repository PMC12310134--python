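#!/usr/bin/env python
"""Map the (zl, za) phase diagram of the zonal schooling model.

Sweeps the alignment radius zl and attraction radius za on a coarse grid,
averaging steady-state polarization P, milling M and nearest-neighbor
distance over seeded Monte-Carlo replicates, and labels each grid point with
its collective phase.  Writes summary and per-replicate CSVs (and an
optional P/M colormap with --plot).

Default grid and replicate counts are scaled down from a full production
sweep; raise --replicates and refine the grids for figure-quality maps.
"""

import argparse
from pathlib import Path

import numpy as np

from threea import EnsembleSpec, SimulationParams, phase_sweep, write_results


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/phase_diagram"))
    ap.add_argument("--replicates", type=int, default=5)
    ap.add_argument("--total-time", type=float, default=500.0)
    ap.add_argument("--plot", action="store_true")
    args = ap.parse_args()

    zl_values = np.arange(1.0, 5.01, 0.5)
    za_values = np.arange(4.0, 14.01, 2.0)
    base = SimulationParams(seed=args.seed, total_time=args.total_time)
    spec = EnsembleSpec(base_params=base, n_replicates=args.replicates,
                        averaging_window=50.0)
    res = phase_sweep(spec, zl_values, za_values)
    write_results(res, args.out, base_seed=args.seed, config={"simulation": base})
    print(res.summary_frame().to_string(index=False))
    print(f"written to {args.out}")

    if args.plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        frame = res.summary_frame()
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, col in zip(axes, ("P_mean", "M_mean")):
            grid = frame.pivot(index="za", columns="zl", values=col)
            im = ax.pcolormesh(grid.columns, grid.index, grid.values,
                               vmin=0, vmax=1, cmap="viridis")
            ax.set_xlabel("$z_l$ (body lengths)")
            ax.set_title(col.replace("_mean", ""))
            fig.colorbar(im, ax=ax)
        axes[0].set_ylabel("$z_a$ (body lengths)")
        fig.tight_layout()
        fig.savefig(args.out / "phase_diagram.png", dpi=150)
        print(f"plot: {args.out / 'phase_diagram.png'}")


if __name__ == "__main__":
    main()
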