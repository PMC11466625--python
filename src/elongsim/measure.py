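"""Simulated readouts: axis length, density, pressure, force, flux, regimes.

All tabulated readouts are returned as :class:`TimeSeriesTable` objects
(bin centers, per-bin mean, per-bin SD across replicates) mirroring the way
simulation replicates are usually aggregated: mean ± SD of the binned mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .construct import TissueType, pd_indices
from .mechanics import Trajectory, _axial_tip_indices

__all__ = [
    "TimeSeriesTable",
    "axis_length",
    "elongation_extent",
    "density_profile",
    "boundary_pressure",
    "axial_push_force",
    "pd_lateral_flux",
    "classify_regime",
    "RegimeResult",
]


@dataclass
class TimeSeriesTable:
    """Binned readout with replicate statistics.

    ``bin_axis`` says what the bins run over: iterations, AP units, or
    distance to the posterior axis end.  ``values`` are per-bin means,
    ``spread`` per-bin SDs (0 when n_replicates == 1); bins are contiguous.
    """

    quantity: str
    bin_axis: str
    bin_edges: np.ndarray
    values: np.ndarray
    spread: np.ndarray
    n_replicates: int = 1
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.values = np.asarray(self.values, float)
        self.spread = np.asarray(self.spread, float)
        if len(self.values) != len(self.bin_edges) - 1:
            raise ValueError("values must have one entry per bin")
        if np.any(self.spread[np.isfinite(self.spread)] < 0):
            raise ValueError("spread must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "quantity": self.quantity,
                "bin": self.bin_centers,
                "mean": self.values,
                "sd": self.spread,
                "n": self.n_replicates,
            }
        )
        if self.labels is not None:
            df["label"] = self.labels
        return df


def _as_arrays(obj):
    return (
        np.asarray(obj.positions),
        np.asarray(obj.types),
        np.asarray(obj.ids),
    )


def axis_length(state, anterior: float = 0.0) -> float:
    """Axis length: mean AP position of the 4 posterior-most axial cells,
    measured from the anterior wall.  AP ties are broken by cell id."""
    tip = _axial_tip_indices(state)
    return float(np.asarray(state.positions)[tip, 0].mean() - anterior)


def elongation_extent(trajectory: Trajectory) -> float:
    """Ratio of the final axis length over the length immediately after the
    perturbation (or over the initial length for unperturbed runs)."""
    snaps = trajectory.snapshots
    if len(snaps) < 2:
        raise ValueError("trajectory must span at least two snapshots")
    if trajectory.perturbation_snapshot_index is not None:
        start = snaps[trajectory.perturbation_snapshot_index]
    else:
        start = snaps[0]
    l0 = axis_length(start)
    if l0 <= 0:
        raise ValueError("initial axis length is zero")
    return axis_length(snaps[-1]) / l0


def density_profile(
    state,
    grid_size: float = 1.0,
    band_width: float = 1.0,
    half_width: float | None = None,
    ppsm_extent: float = 5.0,
    max_distance: float | None = None,
) -> TimeSeriesTable:
    """PSM cell counts per grid cell, as a function of distance to the
    posterior axis end.

    The field is tiled into ``grid_size`` x ``grid_size`` grids; counts of
    PSM cells are aggregated per ``band_width`` band of distance anterior to
    the posterior-most axial cell.  Bands within ``ppsm_extent`` of the end
    are labeled pPSM, the rest aPSM.  The per-band value is the mean count
    per grid cell and the spread the SD across that band's grid cells.
    """
    if grid_size <= 0:
        raise ValueError("grid_size must be positive")
    pos, types, _ = _as_arrays(state)
    axial = types == TissueType.AXIAL.value
    if not axial.any():
        raise ValueError("density profile needs axial cells to define the axis end")
    ax_end = pos[axial, 0].max()
    psm = types == TissueType.PSM.value
    dist = ax_end - pos[psm, 0]
    ml = pos[psm, 1]
    keep = dist >= 0
    dist, ml = dist[keep], ml[keep]
    if max_distance is None:
        max_distance = float(np.ceil(dist.max())) if len(dist) else band_width
    n_bands = max(int(np.ceil(max_distance / band_width)), 1)
    edges = band_width * np.arange(n_bands + 1)
    if half_width is None:
        hw = getattr(getattr(state, "boundary", None), "half_width", None)
        half_width = hw if hw is not None else float(np.abs(ml).max()) + grid_size
    ml_edges = np.arange(-half_width, half_width + grid_size * 0.5, grid_size)
    values = np.full(n_bands, np.nan)
    spread = np.full(n_bands, np.nan)
    labels = np.empty(n_bands, dtype=object)
    for b in range(n_bands):
        in_band = (dist >= edges[b]) & (dist < edges[b + 1])
        n_ap = max(int(round(band_width / grid_size)), 1)
        counts, _, _ = np.histogram2d(
            dist[in_band],
            ml[in_band],
            bins=[np.linspace(edges[b], edges[b + 1], n_ap + 1), ml_edges],
        )
        values[b] = counts.mean()
        spread[b] = counts.std()
        labels[b] = "pPSM" if edges[b + 1] <= ppsm_extent else "aPSM"
    return TimeSeriesTable(
        quantity="grid_density",
        bin_axis="distance_to_axis_end",
        bin_edges=edges,
        values=values,
        spread=spread,
        n_replicates=1,
        labels=labels,
    )


def _replicate_table(
    quantity: str, bin_axis: str, edges: np.ndarray, per_rep: list[np.ndarray],
    labels=None,
) -> TimeSeriesTable:
    stack = np.vstack(per_rep)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0)
    return TimeSeriesTable(
        quantity=quantity,
        bin_axis=bin_axis,
        bin_edges=edges,
        values=mean,
        spread=sd,
        n_replicates=len(per_rep),
        labels=labels,
    )


def boundary_pressure(
    trajectories: Trajectory | list[Trajectory],
    bin_width: float = 1.0,
    max_ap: float | None = None,
    psm_only: bool = True,
    iteration_range: tuple[int, int] | None = None,
) -> TimeSeriesTable:
    """Boundary pressure along AP: summed wall-collision impulses of PSM
    cells per AP bin, normalized per iteration, averaged over replicates.
    ``iteration_range`` restricts the tally to an iteration window (e.g.
    after a perturbation)."""
    trajs = [trajectories] if isinstance(trajectories, Trajectory) else list(trajectories)
    if max_ap is None:
        ap_max = 0.0
        for tr in trajs:
            if len(tr.collisions):
                ap_max = max(ap_max, float(tr.collisions["ap"].max()))
        max_ap = max(np.ceil(ap_max), bin_width)
    edges = np.arange(0.0, max_ap + bin_width * 0.5, bin_width)
    per_rep = []
    any_records = False
    for tr in trajs:
        rec = tr.collisions
        if psm_only and len(rec):
            rec = rec[rec["is_psm"]]
        n_iter = max(tr.n_iterations, 1)
        if iteration_range is not None and len(rec):
            lo, hi = iteration_range
            rec = rec[(rec["iteration"] >= lo) & (rec["iteration"] < hi)]
            n_iter = max(hi - lo, 1)
        if len(rec) == 0:
            per_rep.append(np.zeros(len(edges) - 1))
            continue
        any_records = True
        sums, _ = np.histogram(rec["ap"], bins=edges, weights=rec["impulse"])
        per_rep.append(sums / n_iter)
    if not any_records:
        warnings.warn("collision log empty: boundary pressure is all zero",
                      stacklevel=2)
    return _replicate_table("boundary_pressure", "AP_unit", edges, per_rep)


def _bin_series(iters: np.ndarray, values: np.ndarray, bin_width: int,
                start: int = 0) -> tuple[np.ndarray, np.ndarray]:
    stop = int(iters.max()) + 1
    edges = np.arange(start, stop + bin_width, bin_width, dtype=float)
    idx = np.digitize(iters, edges) - 1
    out = np.full(len(edges) - 1, np.nan)
    for b in range(len(out)):
        sel = idx == b
        if sel.any():
            out[b] = values[sel].mean()
    return edges, out


def axial_push_force(
    trajectories: Trajectory | list[Trajectory],
    bin_width: int = 200,
) -> TimeSeriesTable:
    """A-to-P force on the posterior-most axial cells, binned per
    ``bin_width`` iterations and averaged over replicates."""
    trajs = [trajectories] if isinstance(trajectories, Trajectory) else list(trajectories)
    per_rep = []
    edges = None
    for tr in trajs:
        if tr.axial_force is None:
            raise ValueError(
                "force recording was disabled for this run; re-run with "
                "record_forces=True"
            )
        e, v = _bin_series(tr.iterations, tr.axial_force, bin_width)
        if edges is None or len(e) < len(edges):
            edges = e
        per_rep.append(v)
    m = len(edges) - 1
    per_rep = [v[:m] for v in per_rep]
    return _replicate_table("axial_push_force", "iteration", edges, per_rep)


def pd_lateral_flux(
    trajectories: Trajectory | list[Trajectory],
    bin_width: int = 200,
    pd_half_width: float = 1.0,
    signed: bool = False,
) -> TimeSeriesTable:
    """Medial-lateral speed of progenitor-domain cells per iteration bin.

    PD membership is recomputed per snapshot; each PD cell present in two
    consecutive snapshots contributes |ML displacement| / iterations (signed
    variant: positive = away from the midline).  Bins without any PD cell
    are NaN (missing), not zero.
    """
    trajs = [trajectories] if isinstance(trajectories, Trajectory) else list(trajectories)
    per_rep = []
    max_iter = max(int(tr.iterations.max()) for tr in trajs)
    edges = np.arange(0, max_iter + bin_width, bin_width, dtype=float)
    for tr in trajs:
        snaps = tr.snapshots
        if len(snaps) < 2:
            raise ValueError("need at least two snapshots for flux")
        samples_iter, samples_val = [], []
        for s0, s1 in zip(snaps[:-1], snaps[1:]):
            dt_iter = s1.iteration - s0.iteration
            if dt_iter <= 0:
                continue
            try:
                idx0 = pd_indices(s0, half_width=pd_half_width)
            except ValueError:
                continue
            if len(idx0) == 0:
                continue
            ids0 = s0.ids[idx0]
            lookup = {int(i): k for k, i in enumerate(s1.ids)}
            for k, cid in zip(idx0, ids0):
                j = lookup.get(int(cid))
                if j is None:
                    continue
                dml = s1.positions[j, 1] - s0.positions[k, 1]
                if signed:
                    out_dir = np.sign(s0.positions[k, 1]) or 1.0
                    val = (dml * out_dir) / dt_iter
                else:
                    val = abs(dml) / dt_iter
                samples_iter.append(0.5 * (s0.iteration + s1.iteration))
                samples_val.append(val)
        v = np.full(len(edges) - 1, np.nan)
        if samples_iter:
            si = np.asarray(samples_iter)
            sv = np.asarray(samples_val)
            idx = np.digitize(si, edges) - 1
            for b in range(len(v)):
                sel = idx == b
                if sel.any():
                    v[b] = sv[sel].mean()
        per_rep.append(v)
    return _replicate_table("pd_lateral_flux", "iteration", edges, per_rep)


@dataclass
class RegimeResult:
    """Outcome of the displacement-field classification."""

    label: str  # CONVERGENCE, ELONGATION or UNDETERMINED
    ratio: float  # elongation / convergence summed magnitudes
    convergence_total: float
    elongation_total: float
    per_cell: pd.DataFrame = field(repr=False, default=None)


def classify_regime(
    trajectory: Trajectory,
    threshold: float = 1.0,
) -> RegimeResult:
    """Classify the run's dominant collective movement.

    Each PSM or axial cell's net displacement (first vs last snapshot) is
    decomposed into a convergence component — the magnitude of its ML
    displacement, i.e. motion along the convergence-extension axis of the
    bilaterally symmetric field — and an elongation component — its
    posterior AP displacement (zero if the cell moved anteriorly).  The run
    is labeled by whichever component dominates the summed magnitudes; the
    continuous elongation/convergence ratio is returned for transition
    detection.
    """
    snaps = trajectory.snapshots
    if len(snaps) < 2:
        raise ValueError("trajectory must span at least two snapshots")
    s0, s1 = snaps[0], snaps[-1]
    lookup = {int(i): k for k, i in enumerate(s1.ids)}
    rows = []
    for k, cid in enumerate(s0.ids):
        if s0.types[k] == TissueType.POSTERIOR.value:
            continue
        j = lookup.get(int(cid))
        if j is None:
            continue
        conv = abs(s1.positions[j, 1] - s0.positions[k, 1])
        elong = max(0.0, s1.positions[j, 0] - s0.positions[k, 0])
        rows.append(
            (
                int(cid),
                TissueType(int(s0.types[k])).name,
                conv,
                elong,
                "CONVERGENCE" if conv > elong else
                ("ELONGATION" if elong > conv else "UNDETERMINED"),
            )
        )
    per_cell = pd.DataFrame(
        rows, columns=["id", "type", "convergence", "elongation", "label"]
    )
    c_total = float(per_cell["convergence"].sum())
    e_total = float(per_cell["elongation"].sum())
    if c_total == 0 and e_total == 0:
        label, ratio = "UNDETERMINED", np.nan
    else:
        ratio = e_total / c_total if c_total > 0 else np.inf
        label = "ELONGATION" if ratio > threshold else "CONVERGENCE"
    return RegimeResult(
        label=label,
        ratio=ratio,
        convergence_total=c_total,
        elongation_total=e_total,
        per_cell=per_cell,
    )
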