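"""In-silico mechanical perturbations of the elongating axis.

Analogues of the embryo manipulations: pulling (positive strain) and
compression (negative strain) applied either uniformly along AP or as an
exponentially graded displacement that affects posterior cells most;
deletion of posterior-PSM cells; and switching the progenitor influx rate.
Strain perturbations move positions only and apply instantaneously between
iterations — the tissue's own mechanics then responds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .construct import TissueType

__all__ = [
    "PerturbationSpec",
    "apply_global_strain",
    "apply_graded_strain",
    "delete_ppsm_cells",
    "apply",
]

_KINDS = ("GLOBAL_STRAIN", "GRADED_STRAIN", "DELETE_PPSM", "SET_INFLUX")


@dataclass
class PerturbationSpec:
    """One perturbation event.

    ``strain`` is the signed total AP strain (negative = compression;
    experiments reached about ±10-15%).  ``affected_fraction`` is the
    fraction of cells, counted from the posterior, displaced by graded
    strain (default 0.75).  ``magnitude_parameter`` is the amplitude unit of
    the strong pull/compression conditions (80 in the published runs); it is
    stored and reported with outputs while the physical strain remains the
    controlling input.  ``decay_length`` of the exponential grading defaults
    to one third of the affected zone's AP extent.
    """

    kind: str
    strain: float = 0.0
    affected_fraction: float = 0.75
    magnitude_parameter: float = 80.0
    deletion_fraction: float = 0.0
    decay_length: float | None = None
    apply_at_iteration: int = 0
    influx_rate: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind in ("GLOBAL_STRAIN", "GRADED_STRAIN"):
            if not (0.0 < abs(self.strain) <= 0.5):
                raise ValueError("|strain| must lie in (0, 0.5]")
        if not (0.0 < self.affected_fraction <= 1.0):
            raise ValueError("affected_fraction must lie in (0, 1]")
        if not (0.0 <= self.deletion_fraction <= 1.0):
            raise ValueError("deletion_fraction must lie in [0, 1]")
        if self.kind == "SET_INFLUX" and self.influx_rate is None:
            raise ValueError("SET_INFLUX requires influx_rate")


def apply_global_strain(state, strain: float):
    """Rescale every AP coordinate by (1 + strain) about the anterior wall.

    ML (and DV) coordinates are untouched.  Posterior passive cells are
    displaced along with everything else.
    """
    if state.n_cells == 0:
        raise ValueError("cannot strain an empty state")
    anterior = 0.0
    state.positions[:, 0] = anterior + (1.0 + strain) * (
        state.positions[:, 0] - anterior
    )
    return state


def apply_graded_strain(
    state,
    strain: float,
    affected_fraction: float = 0.75,
    decay_length: float | None = None,
):
    """Exponentially graded AP displacement, largest at the posterior end.

    Cells in the posterior ``affected_fraction`` (by AP rank) receive a
    displacement A * exp((a - a_max) / decay_length); the amplitude A is
    set so the total AP strain of the whole field equals ``strain`` exactly.
    Anterior cells do not move; the map is monotone, so AP order is
    preserved.
    """
    if state.n_cells == 0:
        raise ValueError("cannot strain an empty state")
    a = state.positions[:, 0]
    a_min, a_max = float(a.min()), float(a.max())
    extent = a_max - a_min
    if extent <= 0:
        raise ValueError("degenerate AP extent")
    threshold = float(np.quantile(a, 1.0 - affected_fraction))
    affected = a >= threshold
    if decay_length is None:
        zone = a_max - threshold
        decay_length = zone / 3.0 if zone > 0 else extent / 3.0
    if decay_length <= 0:
        raise ValueError("decay_length must be positive")
    amplitude = strain * extent
    if amplitude < 0 and -amplitude >= decay_length:
        raise ValueError(
            "compression too strong for the decay length: AP order would invert"
        )
    delta = amplitude * np.exp((a[affected] - a_max) / decay_length)
    state.positions[affected, 0] = a[affected] + delta
    return state


def ppsm_indices(state, extent: float = 5.0) -> np.ndarray:
    """Row indices of posterior-PSM cells: PSM within ``extent`` AP units
    anterior of (and including) the posterior-most axial cell."""
    axial = state.types == TissueType.AXIAL.value
    if not axial.any():
        raise ValueError("pPSM region is undefined without axial cells")
    ax_end = state.positions[axial, 0].max()
    x = state.positions[:, 0]
    sel = (state.types == TissueType.PSM.value) & (x > ax_end - extent) & (x <= ax_end)
    return np.flatnonzero(sel)


def delete_ppsm_cells(
    state,
    deletion_fraction: float,
    rng: np.random.Generator | None = None,
    extent: float = 5.0,
):
    """Remove a uniformly sampled fraction of posterior-PSM cells.

    Sampling is without replacement and deterministic under the state's (or
    a supplied) seeded generator; exactly round(fraction * n_region) cells
    are removed.
    """
    if not (0.0 <= deletion_fraction <= 1.0):
        raise ValueError("deletion_fraction must lie in [0, 1]")
    region = ppsm_indices(state, extent=extent)
    if len(region) == 0:
        raise ValueError("pPSM region holds no cells")
    if deletion_fraction == 0.0:
        return state
    if deletion_fraction == 1.0:
        warnings.warn(
            "deleting all pPSM cells: without influx the tissue will collapse",
            stacklevel=2,
        )
    rng = rng or state.rng
    n_remove = int(round(deletion_fraction * len(region)))
    drop = rng.choice(region, size=n_remove, replace=False)
    keep = np.setdiff1d(np.arange(state.n_cells), drop)
    state.positions = state.positions[keep]
    state.types = state.types[keep]
    state.ids = state.ids[keep]
    state.radii = state.radii[keep]
    state.adhesion_distances = state.adhesion_distances[keep]
    state.motility_vectors = state.motility_vectors[keep]
    return state


def apply(state, spec: PerturbationSpec):
    """Dispatch one :class:`PerturbationSpec` onto a simulation state."""
    if spec.kind == "GLOBAL_STRAIN":
        return apply_global_strain(state, spec.strain)
    if spec.kind == "GRADED_STRAIN":
        return apply_graded_strain(
            state, spec.strain, spec.affected_fraction, spec.decay_length
        )
    if spec.kind == "DELETE_PPSM":
        return delete_ppsm_cells(state, spec.deletion_fraction)
    if spec.kind == "SET_INFLUX":
        return state  # the run loop swaps its influx rate
    raise ValueError(f"unknown perturbation kind {spec.kind!r}")
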