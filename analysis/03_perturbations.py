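"""Mechanical perturbation readouts: pressure, push force, progenitor flux.

Runs the perturbation_readouts recipe (graded pulling, graded compression,
pPSM deletion, unperturbed controls) and reports the direction of effect of
each perturbation on boundary pressure along the AP axis, the axial
pushing force, and the progenitor-domain lateral speeds.
"""

import argparse
from pathlib import Path

import numpy as np

from elongsim import measure
from elongsim.recipes import run_recipe

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--replicates", type=int, default=10)
    args = ap.parse_args()

    bundle = run_recipe(
        "perturbation_readouts",
        overrides={"replicates": args.replicates},
        out_dir=OUT,
        seed=args.seed,
    )
    trajs = bundle["trajectories"]
    window = (1000, 1500)  # immediately after the perturbation
    ctrl = measure.boundary_pressure(trajs["control"],
                                     iteration_range=window, max_ap=25)
    tip = np.mean([measure.axis_length(t.snapshots[-1])
                   for t in trajs["control"]])
    b = ctrl.bin_centers
    ppsm = (b > tip - 5) & (b <= tip + 1)
    print(f"pPSM window: AP {tip - 5:.1f}..{tip + 1:.1f}")
    for name in ("pulled", "compressed", "deleted"):
        tab = measure.boundary_pressure(trajs[name], iteration_range=window,
                                        max_ap=25)
        d = tab.values - ctrl.values
        print(f"{name:>10}: dP pPSM {d[ppsm].mean():+.3f}, "
              f"global {d.mean():+.3f}")
    for name in ("pulled", "compressed"):
        f = measure.axial_push_force(trajs[name]).values
        f0 = measure.axial_push_force(trajs["control"]).values
        x = measure.pd_lateral_flux(trajs[name]).values
        x0 = measure.pd_lateral_flux(trajs["control"]).values
        print(f"{name:>10}: dF(early) {np.nanmean(f[5:7] - f0[5:7]):+.3f}, "
              f"flux post {np.nanmean(x[5:]):.5f} "
              f"(control {np.nanmean(x0[5:]):.5f})")


if __name__ == "__main__":
    main()
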