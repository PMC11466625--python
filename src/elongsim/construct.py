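"""Initial multi-tissue layouts for the posterior body axis.

The construct emulates the tissue arrangement of the elongating posterior
body axis: a passive central axial column (notochord + neural tube merged
into one tissue), bilaterally symmetric presomitic mesoderm (PSM) blocks,
a progenitor domain (PD) of PSM-type cells on the posterior midline, and an
optional cap of passive posterior cells.  The field is confined by rigid
anterior and lateral walls (plus dorsal/ventral walls in 3D); the posterior
end is open so the axis can elongate.

All lengths are in model units where one cell diameter = 1 (radius 0.5).
Cells are placed on a jittered lattice at near-contact spacing, which gives
the tissue the confluent, slightly compressed starting state whose
relaxation (together with PSM cell motility) drives expansion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "TissueType",
    "CellRecord",
    "Wall",
    "BoundaryGeometry",
    "LayoutSpec",
    "TissueConstruct",
    "build_construct",
    "pd_mask",
    "CELL_RADIUS",
    "ADHESION_DISTANCE_MULTIPLIER",
]

#: Common cell radius in model length units (one diameter = 1 unit).
CELL_RADIUS = 0.5

#: Maximum adhesion distance, expressed as a multiple of the cell radius.
ADHESION_DISTANCE_MULTIPLIER = {
    "AXIAL": 1.1,
    "PSM": 1.25,
    "POSTERIOR": 1.1,
}


class TissueType(enum.IntEnum):
    """Cell/tissue identity driving all parameter lookups."""

    AXIAL = 0
    PSM = 1
    POSTERIOR = 2


_ADH_MULT_BY_CODE = np.array(
    [ADHESION_DISTANCE_MULTIPLIER[t.name] for t in TissueType]
)


@dataclass
class CellRecord:
    """A single agent: position, identity and interaction geometry.

    ``position`` uses axis 0 = AP (increasing posteriorly), axis 1 = ML
    (midline at 0) and, in 3D, axis 2 = DV.  ``adhesion_distance`` is the
    maximum range of the adhesive interaction (R_A), at least the radius.
    ``motility_vector`` is a unit direction for motile cells, zero otherwise.
    """

    id: int
    position: np.ndarray
    tissue_type: TissueType
    radius: float = CELL_RADIUS
    adhesion_distance: float | None = None
    motility_vector: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.adhesion_distance is None:
            mult = ADHESION_DISTANCE_MULTIPLIER[TissueType(self.tissue_type).name]
            self.adhesion_distance = self.radius * mult
        if self.motility_vector is None:
            self.motility_vector = np.zeros_like(self.position)
        else:
            self.motility_vector = np.asarray(self.motility_vector, dtype=float)
        if self.radius <= 0:
            raise ValueError("cell radius must be positive")
        if self.adhesion_distance < self.radius:
            raise ValueError("adhesion distance must be >= radius")


class Wall(NamedTuple):
    """A rigid plane: cells are confined to ``inward * (coord_along_axis - coord) >= 0``."""

    name: str
    axis: int
    coord: float
    inward: int  # +1 or -1


@dataclass(frozen=True)
class BoundaryGeometry:
    """Rigid confinement of the simulated field.

    The anterior wall sits at AP = 0 and the lateral walls at ML =
    ±``half_width``.  In 3D, dorsal/ventral walls sit at DV = ±``half_depth``.
    The posterior end carries no wall; ``posterior_mode`` states whether a
    cap of passive posterior cells occupies it instead ("PASSIVE_CELLS") or
    it is left empty ("FREE").  ``field_length`` is the AP extent of the
    initial construct.
    """

    field_length: float = 15.0
    half_width: float = 5.0
    half_depth: float | None = None
    posterior_mode: str = "PASSIVE_CELLS"

    def __post_init__(self) -> None:
        if self.posterior_mode not in ("FREE", "PASSIVE_CELLS"):
            raise ValueError(f"unknown posterior_mode {self.posterior_mode!r}")
        if self.field_length <= 0 or self.half_width <= 0:
            raise ValueError("field_length and half_width must be positive")

    def walls(self, dimension: int) -> tuple[Wall, ...]:
        walls = [
            Wall("anterior", 0, 0.0, +1),
            Wall("left", 1, -self.half_width, +1),
            Wall("right", 1, +self.half_width, -1),
        ]
        if dimension == 3:
            if self.half_depth is None:
                raise ValueError("half_depth must be set for 3D geometry")
            walls += [
                Wall("ventral", 2, -self.half_depth, +1),
                Wall("dorsal", 2, +self.half_depth, -1),
            ]
        return tuple(walls)


@dataclass(frozen=True)
class LayoutSpec:
    """Proportions of the initial tissue arrangement.

    The axial column is 2 cell diameters wide (``axial_half_width`` = 1) and
    runs from the anterior wall to ``axial_length``.  The PD occupies the
    midline from the axial end over ``pd_length`` units; the remaining
    posterior stretch holds the passive cap.  ``spacing`` is the lattice
    constant of the near-contact packing; ``jitter`` the uniform positional
    noise per coordinate (±10% of a diameter by default).
    """

    spacing: float = 0.6
    spacing_3d: float = 0.38
    axial_half_width: float = 1.0
    axial_length: float = 10.0
    pd_length: float = 2.0
    jitter: float = 0.1
    wall_margin: float = 0.3


@dataclass
class TissueConstruct:
    """Full initial condition: cell arrays, boundary geometry and seed."""

    ids: np.ndarray
    positions: np.ndarray
    types: np.ndarray
    radii: np.ndarray
    adhesion_distances: np.ndarray
    boundary: BoundaryGeometry
    dimension: int
    seed: int

    def __post_init__(self) -> None:
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("cell ids must be unique")

    @property
    def n_cells(self) -> int:
        return len(self.ids)

    def counts(self) -> dict[str, int]:
        return {
            t.name: int(np.sum(self.types == t.value)) for t in TissueType
        }

    def to_records(self) -> list[CellRecord]:
        return [
            CellRecord(
                id=int(i),
                position=p.copy(),
                tissue_type=TissueType(int(t)),
                radius=float(r),
                adhesion_distance=float(a),
            )
            for i, p, t, r, a in zip(
                self.ids, self.positions, self.types, self.radii,
                self.adhesion_distances,
            )
        ]

    def to_frame(self) -> pd.DataFrame:
        cols = {"id": self.ids, "type": [TissueType(int(t)).name for t in self.types]}
        for k, name in enumerate("xyz"[: self.dimension]):
            cols[name] = self.positions[:, k]
        cols["radius"] = self.radii
        cols["adhesion_distance"] = self.adhesion_distances
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, boundary: BoundaryGeometry | None = None,
                 seed: int = 0) -> "TissueConstruct":
        df = pd.read_csv(path)
        dim = 3 if "z" in df.columns else 2
        pos = df[list("xyz"[:dim])].to_numpy(float)
        types = np.array([TissueType[t].value for t in df["type"]], dtype=np.int8)
        if boundary is None:
            boundary = BoundaryGeometry(
                half_depth=float(np.abs(pos[:, 2]).max()) + 1.0 if dim == 3 else None
            )
        return cls(
            ids=df["id"].to_numpy(np.int64),
            positions=pos,
            types=types,
            radii=df["radius"].to_numpy(float),
            adhesion_distances=df["adhesion_distance"].to_numpy(float),
            boundary=boundary,
            dimension=dim,
            seed=seed,
        )

    def write_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("construct")
            g.create_dataset("ids", data=self.ids)
            g.create_dataset("positions", data=self.positions)
            g.create_dataset("types", data=self.types)
            g.create_dataset("radii", data=self.radii)
            g.create_dataset("adhesion_distances", data=self.adhesion_distances)
            g.attrs["dimension"] = self.dimension
            g.attrs["seed"] = self.seed
            g.attrs["field_length"] = self.boundary.field_length
            g.attrs["half_width"] = self.boundary.half_width
            g.attrs["posterior_mode"] = self.boundary.posterior_mode
            if self.boundary.half_depth is not None:
                g.attrs["half_depth"] = self.boundary.half_depth


def _axis_sites(lo: float, hi: float, spacing: float) -> np.ndarray:
    """Evenly spaced sites spanning [lo, hi] at close to the requested spacing."""
    span = hi - lo
    if span <= 0:
        return np.array([0.5 * (lo + hi)])
    n = max(int(round(span / spacing)) + 1, 2)
    return np.linspace(lo, hi, n)


def _symmetric_rows(half_extent: float, spacing: float) -> np.ndarray:
    """Row coordinates symmetric about 0: 0, ±s, ±2s, ... within ±half_extent."""
    k = int(np.floor(half_extent / spacing))
    rows = spacing * np.arange(-k, k + 1)
    return rows


def _flank_rows(inner: float, outer: float, spacing: float) -> np.ndarray:
    """Mirror-symmetric rows for the lateral PSM blocks, outside ±inner."""
    pos = np.arange(inner + 0.5 * spacing, outer + 1e-12, spacing)
    return np.concatenate([-pos[::-1], pos])


def _region_sites(dimension: int, geometry: BoundaryGeometry,
                  layout: LayoutSpec) -> dict[str, np.ndarray]:
    """Lattice sites per tissue region (before jitter and subsampling)."""
    s = layout.spacing if dimension == 2 else layout.spacing_3d
    m = layout.wall_margin
    L = geometry.field_length
    hw = geometry.half_width

    x_all = _axis_sites(m, L - s / 2.0, s)
    ax_end = layout.axial_length
    pd_end = layout.axial_length + layout.pd_length

    x_axial = x_all[x_all <= ax_end]
    x_pd = x_all[(x_all > ax_end) & (x_all <= pd_end)]
    x_cap = x_all[x_all > pd_end]

    y_axial = _symmetric_rows(layout.axial_half_width, s)
    y_psm = _flank_rows(layout.axial_half_width, hw - m, s)
    y_full = np.sort(np.concatenate([y_axial, y_psm]))

    def grid(xs: np.ndarray, ys: np.ndarray, zs: np.ndarray | None) -> np.ndarray:
        if len(xs) == 0 or len(ys) == 0:
            return np.empty((0, dimension))
        if dimension == 2:
            xx, yy = np.meshgrid(xs, ys, indexing="ij")
            return np.column_stack([xx.ravel(), yy.ravel()])
        xx, yy, zz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    zs = None
    if dimension == 3:
        if geometry.half_depth is None:
            raise ValueError("3D construct requires geometry.half_depth")
        zs = _symmetric_rows(geometry.half_depth - m, s)

    # PSM flanks run alongside the axial column and the PD; the passive cap
    # owns the full width of the field posterior of the PD.
    x_flank = x_all[x_all <= pd_end]
    regions = {
        "AXIAL": grid(x_axial, y_axial, zs),
        "PSM_FLANK": grid(x_flank, y_psm, zs),
        "PD": grid(x_pd, y_axial, zs),
    }
    if geometry.posterior_mode == "PASSIVE_CELLS":
        regions["POSTERIOR"] = grid(x_cap, y_full, zs)
    else:
        regions["POSTERIOR"] = np.empty((0, dimension))
    return regions


#: Default total cell count of the 3D construct.
DEFAULT_3D_TOTAL = 7920


def build_construct(
    dimension: int = 2,
    counts: Mapping[str, int] | None = None,
    geometry: BoundaryGeometry | None = None,
    layout: LayoutSpec | None = None,
    seed: int = 0,
    total: int | None = None,
) -> TissueConstruct:
    """Generate the initial multi-tissue construct.

    Parameters
    ----------
    dimension:
        2 or 3.
    counts:
        Optional per-tissue cell counts (keys AXIAL, PSM, POSTERIOR).  Each
        tissue's cells are subsampled from its full lattice; requesting more
        cells than the region holds at minimum spacing is an error.  When
        omitted the full lattice is used (2D: ~300-500 cells; 3D: trimmed to
        ``total``, 7920 by default).
    geometry, layout:
        Boundary geometry and layout proportions; defaults match the
        standard field (length 15, half-width 5, 3D half-depth 2); the default
        2D lattice yields 375 cells.
    seed:
        Seeds the lattice jitter and any subsampling; the construct is a
        pure function of all arguments.
    """
    if dimension not in (2, 3):
        raise ValueError("dimension must be 2 or 3")
    if geometry is None:
        geometry = BoundaryGeometry(half_depth=2.0 if dimension == 3 else None)
    if dimension == 3 and geometry.half_depth is None:
        raise ValueError("3D construct requires geometry.half_depth")
    layout = layout or LayoutSpec()
    rng = np.random.default_rng(seed)

    regions = _region_sites(dimension, geometry, layout)
    # PD cells are PSM-type progenitors on the posterior midline.
    sites = {
        "AXIAL": regions["AXIAL"],
        "PSM": np.vstack([regions["PSM_FLANK"], regions["PD"]]),
        "POSTERIOR": regions["POSTERIOR"],
    }

    if counts is not None:
        for tissue, n in counts.items():
            cap = len(sites[tissue])
            if n > cap:
                raise ValueError(
                    f"requested {n} {tissue} cells but the {tissue} region holds "
                    f"at most {cap} at minimum spacing"
                )
            if n < cap:
                keep = np.sort(rng.choice(cap, size=n, replace=False))
                sites[tissue] = sites[tissue][keep]
    elif dimension == 3:
        target = DEFAULT_3D_TOTAL if total is None else total
        n_other = len(sites["AXIAL"]) + len(sites["POSTERIOR"])
        n_psm_target = target - n_other
        cap = len(sites["PSM"])
        if n_psm_target < 0 or n_psm_target > cap:
            raise ValueError(
                f"requested total {target} cells but the PSM region holds at "
                f"most {cap} (other tissues: {n_other}) at minimum spacing"
            )
        keep = np.sort(rng.choice(cap, size=n_psm_target, replace=False))
        sites["PSM"] = sites["PSM"][keep]
    elif total is not None:
        raise ValueError("explicit total is only supported for dimension=3")

    order = ["AXIAL", "PSM", "POSTERIOR"]
    positions = np.vstack([sites[t] for t in order])
    types = np.concatenate(
        [np.full(len(sites[t]), TissueType[t].value, dtype=np.int8) for t in order]
    )
    positions = positions + rng.uniform(
        -layout.jitter, layout.jitter, size=positions.shape
    )

    # Jitter must not push any cell through a rigid wall.
    for wall in geometry.walls(dimension):
        d = wall.inward * (positions[:, wall.axis] - wall.coord)
        bad = d <= 0
        positions[bad, wall.axis] = wall.coord + wall.inward * 1e-3

    radii = np.full(len(positions), CELL_RADIUS)
    adh = radii * _ADH_MULT_BY_CODE[types]
    return TissueConstruct(
        ids=np.arange(len(positions), dtype=np.int64),
        positions=positions,
        types=types,
        radii=radii,
        adhesion_distances=adh,
        boundary=geometry,
        dimension=dimension,
        seed=seed,
    )


def pd_mask(state, half_width: float = 1.0) -> set[int]:
    """Ids of progenitor-domain cells: PSM cells on the midline posterior to
    the axial tissue.

    Works on any object exposing ``ids``, ``positions`` and ``types`` arrays
    (constructs, simulation states, snapshots); recomputable at any
    iteration.  ``half_width`` is the midline ML tolerance (default one cell
    diameter).
    """
    idx = pd_indices(state, half_width)
    return set(int(i) for i in np.asarray(state.ids)[idx])


def pd_indices(state, half_width: float = 1.0) -> np.ndarray:
    """Array-index variant of :func:`pd_mask` (positions array row indices)."""
    types = np.asarray(state.types)
    pos = np.asarray(state.positions)
    axial = types == TissueType.AXIAL.value
    if not axial.any():
        raise ValueError("progenitor domain is undefined without axial cells")
    ax_end = pos[axial, 0].max()
    sel = (types == TissueType.PSM.value) & (pos[:, 0] > ax_end) & (
        np.abs(pos[:, 1]) < half_width
    )
    return np.flatnonzero(sel)
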