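"""Shallow-network surrogate of sweep outputs.

Fits a one-hidden-layer regressor from the five scaled repulsion inputs to
the axial bounding-box length and width on the sweep table produced by
05_sweep_transition.py (70/15/15 train/validation/test split) and reports
the held-out accuracy.  A single-axis slice probes only one input
dimension, so held-out R^2 on it is modest; a full multi-axis grid
(generate_grid mode "full_grid") gives the surrogate real structure to
learn.
"""

import argparse
from pathlib import Path

import pandas as pd

from elongsim.sweep import fit_surrogate

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--hidden", type=int, default=10)
    ap.add_argument("--sweep", type=Path,
                    default=OUT / "sweep_psm_psm.csv")
    args = ap.parse_args()

    if not args.sweep.exists():
        raise SystemExit(f"{args.sweep} not found; run 05_sweep_transition.py "
                         "first")
    df = pd.read_csv(args.sweep)
    res = fit_surrogate(df, hidden_units=args.hidden, split_seed=args.seed)
    res.save(str(OUT / "surrogate"))
    print("surrogate metrics:",
          {k: round(float(v), 4) for k, v in res.metrics.items()})


if __name__ == "__main__":
    main()
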