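"""Parameter-space exploration over the five repulsion coefficients.

The 2D model (no progenitor influx) is run over grids or one-parameter
slices of the five cell-cell repulsion parameters; each run is summarized
by the axial tissue's bounding-box length and width and by the
convergence/elongation classification of its displacement field.  A
one-hidden-layer neural network can be fitted as a cheap surrogate of the
sweep outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import construct as _construct
from . import measure as _measure
from .mechanics import MechanicsParams, run, stable_dt
from .construct import TissueType

__all__ = [
    "SWEEP_RANGES",
    "SweepPoint",
    "scale_value",
    "unscale_value",
    "generate_grid",
    "run_sweep",
    "aggregate_sweep",
    "find_transition",
    "TransitionResult",
    "fit_surrogate",
    "SurrogateResult",
]

#: Explored ranges of the five repulsion coefficients.
SWEEP_RANGES: dict[str, tuple[float, float]] = {
    "psm_psm": (5.0, 45.0),
    "nc_nc": (1.0, 16.0),
    "post_post": (0.1, 1.1),
    "psm_nc": (20.0, 80.0),
    "psm_post": (10.0, 60.0),
}

PARAM_NAMES = tuple(SWEEP_RANGES)


def scale_value(name: str, raw: float) -> float:
    """Min-max normalize a raw coefficient to [0, 1] over its sweep range."""
    lo, hi = SWEEP_RANGES[name]
    return (raw - lo) / (hi - lo)


def unscale_value(name: str, scaled: float) -> float:
    lo, hi = SWEEP_RANGES[name]
    return lo + scaled * (hi - lo)


@dataclass
class SweepPoint:
    """One location in the five-parameter repulsion space."""

    psm_psm: float
    nc_nc: float
    post_post: float
    psm_nc: float
    psm_post: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = SWEEP_RANGES[name]
            v = getattr(self, name)
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                raise ValueError(f"{name}={v} outside sweep range [{lo}, {hi}]")

    def raw(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    def scaled(self) -> dict[str, float]:
        return {n: scale_value(n, getattr(self, n)) for n in PARAM_NAMES}

    def params(self, **overrides) -> MechanicsParams:
        return MechanicsParams.with_repulsion(**self.raw(), **overrides)


def _midpoints() -> dict[str, float]:
    return {n: 0.5 * (lo + hi) for n, (lo, hi) in SWEEP_RANGES.items()}


def generate_grid(
    ranges: Mapping[str, tuple[float, float]] | None = None,
    points_per_axis: int = 3,
    mode: str = "full_grid",
    axis: str = "psm_psm",
    points: int = 17,
) -> list[SweepPoint]:
    """Build sweep inputs: a full grid, or a 1D slice along one parameter
    with the others fixed at their range midpoints."""
    ranges = dict(ranges or SWEEP_RANGES)
    if mode == "one_axis_slice":
        if points < 2:
            raise ValueError("a slice needs at least 2 points")
        mids = _midpoints()
        lo, hi = ranges[axis]
        out = []
        for v in np.linspace(lo, hi, points):
            kw = dict(mids)
            kw[axis] = float(v)
            out.append(SweepPoint(**kw))
        return out
    if mode == "full_grid":
        if points_per_axis < 2:
            raise ValueError("full grid needs at least 2 points per axis")
        axes = [np.linspace(lo, hi, points_per_axis) for lo, hi in
                (ranges[n] for n in PARAM_NAMES)]
        grids = np.meshgrid(*axes, indexing="ij")
        combos = np.column_stack([g.ravel() for g in grids])
        return [SweepPoint(*map(float, row)) for row in combos]
    raise ValueError(f"unknown mode {mode!r}")


def _derive_seed(root: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=int(root), spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(
    points: Sequence[SweepPoint],
    n_iterations: int = 2000,
    replicates: int = 5,
    seed: int = 0,
    construct_kwargs: Mapping | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the 2D no-influx model at each sweep point.

    Returns a tidy frame with one row per point x replicate: the five raw
    and five scaled coefficients, axial bounding-box length and width, the
    elongation/convergence ratio and label, and the replicate seed.  A run
    that fails is flagged (label FAILED) and the sweep continues.  Results
    are deterministic per (point index, replicate, root seed).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    construct_kwargs = dict(construct_kwargs or {})
    # One integration step for the whole sweep, sized for its stiffest
    # coefficient so runs at different points share the same clock.
    hardest = max(hi for _, hi in SWEEP_RANGES.values())
    dt = stable_dt(max_coefficient=hardest)
    rows = []
    iterator = enumerate(points)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc="sweep")
    for p_idx, point in iterator:
        params = point.params(dt=dt)
        for rep in range(replicates):
            run_seed = _derive_seed(seed, p_idx, rep)
            row = {**{f"raw_{n}": v for n, v in point.raw().items()},
                   **{f"scaled_{n}": v for n, v in point.scaled().items()},
                   "point": p_idx, "replicate": rep, "seed": run_seed}
            try:
                cons = _construct.build_construct(
                    dimension=2, seed=run_seed, **construct_kwargs
                )
                traj = run(
                    cons,
                    params,
                    n_iterations=n_iterations,
                    influx_rate=0.0,
                    record_every=n_iterations,
                    seed=run_seed,
                    log_collisions=False,
                    record_forces=False,
                )
                final = traj.snapshots[-1]
                axial = final.types == TissueType.AXIAL.value
                ax_pos = final.positions[axial]
                regime = _measure.classify_regime(traj)
                row.update(
                    length=float(ax_pos[:, 0].max() - ax_pos[:, 0].min()),
                    width=float(ax_pos[:, 1].max() - ax_pos[:, 1].min()),
                    ratio=regime.ratio,
                    label=regime.label,
                )
            except Exception as exc:  # pragma: no cover - defensive
                row.update(length=np.nan, width=np.nan, ratio=np.nan,
                           label="FAILED", error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicates: mean outputs and majority regime label per point."""
    def majority(labels):
        ok = [l for l in labels if l in ("CONVERGENCE", "ELONGATION")]
        if not ok:
            return "FAILED"
        c = ok.count("CONVERGENCE")
        return "CONVERGENCE" if c > len(ok) / 2 else "ELONGATION"

    keys = [c for c in df.columns if c.startswith(("raw_", "scaled_"))] + ["point"]
    agg = df.groupby("point", as_index=False).agg(
        **{k: (k, "first") for k in keys if k != "point"},
        length=("length", "mean"),
        width=("width", "mean"),
        ratio=("ratio", "mean"),
        label=("label", majority),
        n_replicates=("replicate", "size"),
    )
    return agg


@dataclass
class TransitionResult:
    """Location of the convergence-to-elongation regime switch on a slice."""

    scaled_value: float
    raw_value: float
    interval: tuple[float, float]  # scaled (last CONVERGENCE, first ELONGATION)
    monotone: bool
    axis: str


def find_transition(agg: pd.DataFrame, axis: str = "psm_psm") -> TransitionResult:
    """Locate the regime transition on a one-parameter slice.

    Takes the replicate-aggregated slice (majority labels); returns the
    scaled midpoint between the highest value labeled CONVERGENCE and the
    lowest labeled ELONGATION.  Slices whose labels are not monotone along
    the parameter are flagged (``monotone=False``); a single-regime slice is
    an error.
    """
    col = f"scaled_{axis}"
    sub = agg[agg["label"].isin(["CONVERGENCE", "ELONGATION"])].sort_values(col)
    labels = sub["label"].to_numpy()
    x = sub[col].to_numpy(float)
    if "CONVERGENCE" not in labels or "ELONGATION" not in labels:
        raise ValueError("no transition in range: slice shows a single regime")
    hi_c = x[labels == "CONVERGENCE"].max()
    lo_e = x[labels == "ELONGATION"].min()
    # monotone means every CONVERGENCE point lies below every ELONGATION point
    monotone = bool(hi_c < lo_e)
    mid_scaled = 0.5 * (hi_c + lo_e)
    return TransitionResult(
        scaled_value=float(mid_scaled),
        raw_value=float(unscale_value(axis, mid_scaled)),
        interval=(float(hi_c), float(lo_e)),
        monotone=monotone,
        axis=axis,
    )


@dataclass
class SurrogateResult:
    """Fitted sweep surrogate with its held-out metrics."""

    model: object
    x_scaler: object
    y_scaler: object
    targets: tuple[str, ...]
    metrics: dict
    split: dict  # index arrays train/val/test

    def predict(self, scaled_inputs: np.ndarray) -> np.ndarray:
        xs = self.x_scaler.transform(np.asarray(scaled_inputs, float))
        ys = self.model.predict(xs)
        if ys.ndim == 1:
            ys = ys[:, None]
        return self.y_scaler.inverse_transform(ys)

    def save(self, path_prefix: str) -> None:
        """Write portable weight arrays (.npz) plus a JSON metadata sidecar."""
        import json

        np.savez(
            f"{path_prefix}_weights.npz",
            **{f"coef_{i}": c for i, c in enumerate(self.model.coefs_)},
            **{f"intercept_{i}": b for i, b in enumerate(self.model.intercepts_)},
        )
        meta = {
            "targets": list(self.targets),
            "metrics": {k: float(v) for k, v in self.metrics.items()},
            "hidden_units": list(self.model.hidden_layer_sizes)
            if hasattr(self.model.hidden_layer_sizes, "__len__")
            else [self.model.hidden_layer_sizes],
            "activation": self.model.activation,
        }
        with open(f"{path_prefix}_meta.json", "w") as f:
            json.dump(meta, f, indent=2)


def fit_surrogate(
    sweep_df: pd.DataFrame,
    hidden_units: int = 10,
    split_seed: int = 0,
    targets: Sequence[str] = ("length", "width"),
    alphas: Sequence[float] = (1e-4, 1e-2),
) -> SurrogateResult:
    """Fit a one-hidden-layer feed-forward surrogate of the sweep outputs.

    Inputs are the five scaled repulsion coefficients; targets (axial length
    and width by default) are standardized before training.  Samples are
    split 70/15/15 into train/validation/test; the validation split selects
    the regularization strength, the test split yields the reported held-out
    R^2.
    """
    from sklearn.metrics import r2_score
    from sklearn.neural_network import MLPRegressor
    from sklearn.preprocessing import StandardScaler

    df = sweep_df.dropna(subset=list(targets))
    if len(df) < 50:
        raise ValueError("need at least 50 completed sweep samples")
    X = df[[f"scaled_{n}" for n in PARAM_NAMES]].to_numpy(float)
    Y = df[list(targets)].to_numpy(float)
    if np.any(Y.std(axis=0) == 0):
        raise ValueError("degenerate (constant) surrogate targets")

    n = len(df)
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(n)
    n_train = int(round(0.70 * n))
    n_val = int(round(0.15 * n))
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]

    xs = StandardScaler().fit(X[idx_train])
    ys = StandardScaler().fit(Y[idx_train])
    Xt, Yt = xs.transform(X), ys.transform(Y)

    best = None
    for alpha in alphas:
        model = MLPRegressor(
            hidden_layer_sizes=(hidden_units,),
            activation="tanh",
            solver="lbfgs",
            alpha=alpha,
            max_iter=5000,
            random_state=split_seed,
        )
        model.fit(Xt[idx_train], Yt[idx_train])
        r2_val = r2_score(Yt[idx_val], model.predict(Xt[idx_val]))
        if best is None or r2_val > best[0]:
            best = (r2_val, alpha, model)
    r2_val, alpha, model = best
    pred_test = model.predict(Xt[idx_test])
    metrics = {
        "r2_train": r2_score(Yt[idx_train], model.predict(Xt[idx_train])),
        "r2_val": r2_val,
        "r2_test": r2_score(Yt[idx_test], pred_test),
        "alpha": alpha,
    }
    return SurrogateResult(
        model=model,
        x_scaler=xs,
        y_scaler=ys,
        targets=tuple(targets),
        metrics=metrics,
        split={"train": idx_train, "val": idx_val, "test": idx_test},
    )
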