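"""Progenitor influx vs cell density in the posterior PSM.

Runs the influx_feedback recipe (influx on vs off) and summarizes the late
posterior-PSM grid density and the axis-length trajectory for each
condition.  In this model the influx robustly sustains pPSM density; its
effect on the axial-tip advance is negative (inserted progenitors sit in
the tip's path), a known divergence discussed in docs/methods.md.
"""

import argparse
from pathlib import Path

import numpy as np

from elongsim.recipes import run_recipe

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--replicates", type=int, default=20)
    ap.add_argument("--iterations", type=int, default=6000)
    args = ap.parse_args()

    bundle = run_recipe(
        "influx_feedback",
        overrides={"replicates": args.replicates,
                   "n_iterations": args.iterations},
        out_dir=OUT,
        seed=args.seed,
    )
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    for cond in ("influx_on", "influx_off"):
        t = bundle["tables"][f"length_{cond}"]
        ax.plot(t["iteration"], t["mean"], label=cond)
        ax.fill_between(t["iteration"], t["mean"] - t["sd"],
                        t["mean"] + t["sd"], alpha=0.2)
    ax.set_xlabel("iteration"); ax.set_ylabel("axis length (units)")
    ax.legend(frameon=False)
    (OUT / "figures").mkdir(parents=True, exist_ok=True)
    fig.tight_layout(); fig.savefig(OUT / "figures" / "influx_length.png", dpi=150)

    for cond in ("influx_on", "influx_off"):
        dens = bundle["tables"][f"density_{cond}"]
        ppsm = dens.loc[dens["label"] == "pPSM", "mean"].mean()
        final_len = bundle["tables"][f"length_{cond}"]["mean"].iloc[-1]
        print(f"{cond}: final pPSM grid density {ppsm:.3f}, "
              f"final axis length {final_len:.2f}")
    on = bundle["tables"]["density_influx_on"]
    off = bundle["tables"]["density_influx_off"]
    d_on = on.loc[on["label"] == "pPSM", "mean"].mean()
    d_off = off.loc[off["label"] == "pPSM", "mean"].mean()
    print(f"density feedback: influx-off pPSM density is "
          f"{100 * (1 - d_off / d_on):.1f}% below influx-on")


if __name__ == "__main__":
    main()
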