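"""Overdamped center-based mechanics of the multi-tissue model.

Each cell i moves with a velocity set directly by its interactions (inertia
is negligible at tissue scale):

    v_i = sum_j f_ij + f_wall(x_i) + v_mot,i
    x_i <- x_i + v_i * dt

Pairwise interactions use quadratic-falloff potentials.  For center distance
d and cells i, j with radii R_i, R_j and maximum adhesion distances R_iA,
R_jA:

* repulsion, when d < R_i + R_j:   sqrt(c_r^i c_r^j) (1 - d/(R_i+R_j))^2,
  directed j -> i (pushes apart);
* adhesion, when R_i+R_j <= d < R_iA+R_jA:
  sqrt(c_a^i c_a^j) (1 - d/(R_iA+R_jA))^2, directed i -> j;
* zero beyond the adhesion range.

Rigid walls repel with the same falloff when a cell is within one radius of
the wall; every wall contact is logged (wall, AP position, impulse) so that
boundary pressure can be tallied afterwards.  Motile (PSM) cells carry an
active velocity of fixed magnitude whose direction is redrawn uniformly at
random every persistence interval ("directionless" motility); passive axial
and posterior cells have zero motility.

There is no proliferation or apoptosis: cell count changes only through
explicit progenitor influx or deletion operations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
from scipy.spatial import cKDTree

from .construct import (
    CELL_RADIUS,
    BoundaryGeometry,
    CellRecord,
    TissueConstruct,
    TissueType,
    pd_indices,
)

__all__ = [
    "MechanicsParams",
    "SimulationState",
    "Snapshot",
    "Trajectory",
    "pair_velocity",
    "boundary_velocity",
    "motility_velocity",
    "brute_force_velocities",
    "step",
    "add_influx",
    "run",
    "stable_dt",
]

# Homotypic interaction parameters per tissue type (AXIAL, PSM, POSTERIOR).
TYPE_REPULSION = np.array([10.0, 10.0, 10.0])
TYPE_ADHESION = np.array([2.5, 0.05, 1.0])
TYPE_MOTILITY = np.array([0.0, 1.2, 0.0])
TYPE_ADHESION_MULT = np.array([1.1, 1.25, 1.1])


def stable_dt(
    max_coefficient: float = 10.0,
    motility: float = 1.2,
    max_overlap: float = 0.4,
    contacts: int = 3,
    max_step_fraction: float = 0.1,
    radius: float = CELL_RADIUS,
) -> float:
    """Integration step from a maximum-displacement rule.

    The step is chosen so the largest expected per-iteration displacement —
    ``contacts`` simultaneous pair interactions at relative overlap
    ``max_overlap`` with the largest coefficient in play, plus motility —
    stays below ``max_step_fraction`` of a cell radius.  Parameter sweeps
    that raise heterotypic repulsion (up to 80) therefore integrate with a
    proportionally smaller step than default-parameter runs.
    """
    v_max = max_coefficient * max_overlap**2 * contacts + motility
    return max_step_fraction * radius / v_max


def _pair_matrix(per_type: np.ndarray) -> np.ndarray:
    """Geometric-mean combination rule for heterotypic coefficients."""
    v = np.asarray(per_type, dtype=float)
    return np.sqrt(np.outer(v, v))


@dataclass
class MechanicsParams:
    """All interaction coefficients and integration settings.

    ``repulsion`` and ``adhesion`` are symmetric 3x3 type-pair matrices
    indexed by :class:`TissueType`; heterotypic entries default to the
    geometric mean of the homotypic values but can be set directly (the
    parameter sweeps do).  ``motility_persistence`` is the time between
    redraws of a motile cell's direction, in model time units (not
    iterations), so the random-walk statistics are independent of the
    integration step; the default of 1 time unit gives mesenchymal cells an
    effective diffusivity of about 0.7 length^2 per time unit.
    """

    repulsion: np.ndarray = field(default_factory=lambda: _pair_matrix(TYPE_REPULSION))
    adhesion: np.ndarray = field(default_factory=lambda: _pair_matrix(TYPE_ADHESION))
    motility_magnitude: np.ndarray = field(default_factory=lambda: TYPE_MOTILITY.copy())
    adhesion_distance_multiplier: np.ndarray = field(
        default_factory=lambda: TYPE_ADHESION_MULT.copy()
    )
    boundary_repulsion: float = 10.0
    boundary_adhesion: float = 0.0
    dt: float = 0.005
    motility_persistence: float = 1.0

    def __post_init__(self) -> None:
        self.repulsion = np.asarray(self.repulsion, dtype=float)
        self.adhesion = np.asarray(self.adhesion, dtype=float)
        self.motility_magnitude = np.asarray(self.motility_magnitude, dtype=float)
        self.adhesion_distance_multiplier = np.asarray(
            self.adhesion_distance_multiplier, dtype=float
        )
        for name in ("repulsion", "adhesion"):
            m = getattr(self, name)
            if m.shape != (3, 3):
                raise ValueError(f"{name} must be a 3x3 type-pair matrix")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} matrix must be symmetric")
            if (m < 0).any():
                raise ValueError(f"{name} coefficients must be non-negative")
        if (self.motility_magnitude < 0).any():
            raise ValueError("motility magnitudes must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.motility_persistence <= 0:
            raise ValueError("motility_persistence must be positive")

    @property
    def persistence_iterations(self) -> int:
        return max(1, int(round(self.motility_persistence / self.dt)))

    @classmethod
    def default(cls, **overrides) -> "MechanicsParams":
        return cls(**overrides)

    @classmethod
    def with_repulsion(
        cls,
        psm_psm: float | None = None,
        nc_nc: float | None = None,
        post_post: float | None = None,
        psm_nc: float | None = None,
        psm_post: float | None = None,
        **overrides,
    ) -> "MechanicsParams":
        """Params with the five sweepable repulsion coefficients set.

        Homotypic entries default to the standard value (10); unset
        heterotypic entries fall back to the geometric mean of the homotypic
        ones.
        """
        homo = np.array(
            [
                TYPE_REPULSION[0] if nc_nc is None else nc_nc,
                TYPE_REPULSION[1] if psm_psm is None else psm_psm,
                TYPE_REPULSION[2] if post_post is None else post_post,
            ]
        )
        rep = _pair_matrix(homo)
        a, p, q = TissueType.AXIAL, TissueType.PSM, TissueType.POSTERIOR
        if psm_nc is not None:
            rep[a, p] = rep[p, a] = psm_nc
        if psm_post is not None:
            rep[p, q] = rep[q, p] = psm_post
        return cls(repulsion=rep, **overrides)

    def replace(self, **changes) -> "MechanicsParams":
        return dataclasses.replace(self, **changes)


@dataclass
class Snapshot:
    """Recorded state at one iteration (ids, positions, types are copies)."""

    iteration: int
    ids: np.ndarray
    positions: np.ndarray
    types: np.ndarray


# Collision records accumulate as (iteration, wall_index, ap, impulse, is_psm)
_COLLISION_DTYPE = np.dtype(
    [
        ("iteration", np.int64),
        ("wall", np.int8),
        ("ap", np.float64),
        ("impulse", np.float64),
        ("is_psm", np.bool_),
    ]
)


@dataclass
class SimulationState:
    """Mutable simulation state: cell arrays plus bookkeeping."""

    positions: np.ndarray
    types: np.ndarray
    ids: np.ndarray
    radii: np.ndarray
    adhesion_distances: np.ndarray
    motility_vectors: np.ndarray
    boundary: BoundaryGeometry
    rng: np.random.Generator
    iteration: int = 0
    next_id: int = 0
    collision_log: list = field(default_factory=list)
    clamp_events: int = 0
    influx_skipped: int = 0

    @classmethod
    def from_construct(cls, construct: TissueConstruct, seed: int = 0) -> "SimulationState":
        rng = np.random.default_rng(seed)
        state = cls(
            positions=construct.positions.copy(),
            types=construct.types.copy(),
            ids=construct.ids.copy(),
            radii=construct.radii.copy(),
            adhesion_distances=construct.adhesion_distances.copy(),
            motility_vectors=np.zeros_like(construct.positions),
            boundary=construct.boundary,
            rng=rng,
            next_id=int(construct.ids.max()) + 1 if construct.n_cells else 0,
        )
        return state

    @property
    def n_cells(self) -> int:
        return len(self.ids)

    @property
    def dimension(self) -> int:
        return self.positions.shape[1]

    def snapshot(self) -> Snapshot:
        return Snapshot(
            iteration=self.iteration,
            ids=self.ids.copy(),
            positions=self.positions.copy(),
            types=self.types.copy(),
        )

    def collision_array(self) -> np.ndarray:
        """All collision records so far as one structured array."""
        if not self.collision_log:
            return np.empty(0, dtype=_COLLISION_DTYPE)
        return np.concatenate(self.collision_log)

    def redraw_motility(self, params: MechanicsParams) -> None:
        """Redraw unit directions for motile cells, uniform on circle/sphere."""
        motile = params.motility_magnitude[self.types] > 0
        n = int(motile.sum())
        if n == 0:
            self.motility_vectors[:] = 0.0
            return
        if self.dimension == 2:
            ang = self.rng.uniform(0.0, 2.0 * np.pi, size=n)
            dirs = np.column_stack([np.cos(ang), np.sin(ang)])
        else:
            v = self.rng.normal(size=(n, 3))
            norms = np.linalg.norm(v, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            dirs = v / norms
        self.motility_vectors[:] = 0.0
        self.motility_vectors[motile] = dirs


def _unit_random(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.normal(size=dim)
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.eye(dim)[0]


def pair_velocity(
    cell_i: CellRecord,
    cell_j: CellRecord,
    params: MechanicsParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Velocity contribution of cell_j on cell_i (reference implementation).

    Used as the O(N^2) oracle against the vectorized engine; operates on
    single :class:`CellRecord` pairs.  Coincident cells are separated along
    a random unit direction drawn from ``rng`` (seeded tie-break).
    """
    if cell_i.id == cell_j.id:
        raise ValueError("pair_velocity requires distinct cells")
    dvec = np.asarray(cell_i.position, float) - np.asarray(cell_j.position, float)
    d = float(np.linalg.norm(dvec))
    ti, tj = int(cell_i.tissue_type), int(cell_j.tissue_type)
    r_sum = cell_i.radius + cell_j.radius
    a_sum = cell_i.adhesion_distance + cell_j.adhesion_distance
    if d >= a_sum:
        return np.zeros_like(dvec)
    if d < 1e-12:
        rng = rng or np.random.default_rng(0)
        u = _unit_random(rng, len(dvec))
        return params.repulsion[ti, tj] * u
    u = dvec / d
    if d < r_sum:
        mag = params.repulsion[ti, tj] * (1.0 - d / r_sum) ** 2
        return mag * u
    mag = params.adhesion[ti, tj] * (1.0 - d / a_sum) ** 2
    return -mag * u


def boundary_velocity(
    cell: CellRecord,
    boundary: BoundaryGeometry,
    params: MechanicsParams,
) -> tuple[np.ndarray, list[tuple[str, float, float]]]:
    """Wall interaction for one cell: (velocity, impulse records).

    Walls repel with the quadratic falloff once the cell center is within
    one radius; each contact emits (wall name, AP coordinate, impulse
    magnitude) for the pressure tally.  Cells found outside a wall are
    handled by the integrator's clamp, not here.
    """
    dim = len(cell.position)
    vel = np.zeros(dim)
    records: list[tuple[str, float, float]] = []
    mult = params.adhesion_distance_multiplier[int(cell.tissue_type)]
    for wall in boundary.walls(dim):
        d = wall.inward * (cell.position[wall.axis] - wall.coord)
        if d < cell.radius:
            mag = params.boundary_repulsion * (1.0 - max(d, 0.0) / cell.radius) ** 2
            vel[wall.axis] += wall.inward * mag
            records.append((wall.name, float(cell.position[0]), float(mag)))
        elif params.boundary_adhesion > 0 and d < cell.radius * mult:
            mag = params.boundary_adhesion * (1.0 - d / (cell.radius * mult)) ** 2
            vel[wall.axis] -= wall.inward * mag
    return vel, records


def motility_velocity(
    cell: CellRecord,
    params: MechanicsParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Active motility velocity: zero for passive types, magnitude x unit
    direction for motile ones (direction redrawn by the integrator)."""
    mag = params.motility_magnitude[int(cell.tissue_type)]
    if mag == 0:
        return np.zeros_like(np.asarray(cell.position, float))
    direction = np.asarray(cell.motility_vector, float)
    if np.linalg.norm(direction) == 0:
        rng = rng or np.random.default_rng(0)
        direction = _unit_random(rng, len(cell.position))
    return mag * direction


def brute_force_velocities(
    state: SimulationState, params: MechanicsParams
) -> np.ndarray:
    """O(N^2) all-pairs passive velocities via :func:`pair_velocity` —
    the independent oracle for the neighbor-list engine (motility excluded)."""
    records = [
        CellRecord(
            id=int(state.ids[k]),
            position=state.positions[k],
            tissue_type=TissueType(int(state.types[k])),
            radius=float(state.radii[k]),
            adhesion_distance=float(state.adhesion_distances[k]),
        )
        for k in range(state.n_cells)
    ]
    vel = np.zeros_like(state.positions)
    for a in range(len(records)):
        for b in range(len(records)):
            if a == b:
                continue
            vel[a] += pair_velocity(records[a], records[b], params)
        bvel, _ = boundary_velocity(records[a], state.boundary, params)
        vel[a] += bvel
    return vel


def _passive_velocities(
    state: SimulationState,
    params: MechanicsParams,
    log_collisions: bool = True,
) -> np.ndarray:
    """Vectorized pairwise + wall velocities (no motility).

    Neighbor candidates come from a k-d tree queried at the maximum
    adhesion range; wall contacts are appended to the state's collision log
    when ``log_collisions`` is set.
    """
    pos = state.positions
    n, dim = pos.shape
    vel = np.zeros_like(pos)
    if n == 0:
        return vel

    cutoff = float(2.0 * state.adhesion_distances.max())
    pairs = cKDTree(pos).query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        dvec = pos[i] - pos[j]
        d = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
        # Coincident centers: seeded random separation direction.
        zero = d < 1e-12
        if zero.any():
            for k in np.flatnonzero(zero):
                dvec[k] = _unit_random(state.rng, dim)
            d[zero] = 1.0
        r_sum = state.radii[i] + state.radii[j]
        a_sum = state.adhesion_distances[i] + state.adhesion_distances[j]
        ti, tj = state.types[i], state.types[j]
        overlap = d < r_sum
        mag = np.where(
            overlap,
            params.repulsion[ti, tj] * (1.0 - d / r_sum) ** 2,
            -params.adhesion[ti, tj]
            * np.clip(1.0 - d / a_sum, 0.0, None) ** 2,
        )
        f = (mag / d)[:, None] * dvec
        for k in range(dim):
            vel[:, k] += np.bincount(i, weights=f[:, k], minlength=n)
            vel[:, k] -= np.bincount(j, weights=f[:, k], minlength=n)

    walls = state.boundary.walls(dim)
    collisions = []
    is_psm = state.types == TissueType.PSM.value
    for w_idx, wall in enumerate(walls):
        d = wall.inward * (pos[:, wall.axis] - wall.coord)
        contact = d < state.radii
        if contact.any():
            dd = np.clip(d[contact], 0.0, None)
            mag = params.boundary_repulsion * (1.0 - dd / state.radii[contact]) ** 2
            vel[contact, wall.axis] += wall.inward * mag
            if log_collisions:
                rec = np.empty(int(contact.sum()), dtype=_COLLISION_DTYPE)
                rec["iteration"] = state.iteration
                rec["wall"] = w_idx
                rec["ap"] = pos[contact, 0]
                rec["impulse"] = mag
                rec["is_psm"] = is_psm[contact]
                collisions.append(rec)
        if params.boundary_adhesion > 0:
            reach = state.radii * params.adhesion_distance_multiplier[state.types]
            band = (~contact) & (d < reach)
            if band.any():
                mag = params.boundary_adhesion * (1.0 - d[band] / reach[band]) ** 2
                vel[band, wall.axis] -= wall.inward * mag
    if log_collisions and collisions:
        state.collision_log.append(np.concatenate(collisions))
    return vel


def _step_impl(
    state: SimulationState,
    params: MechanicsParams,
    log_collisions: bool,
    tip_indices: np.ndarray | None,
) -> float | None:
    """One forward-Euler iteration in place; optionally returns the summed
    AP interaction force on ``tip_indices`` (pre-integration, no motility)."""
    if state.iteration % params.persistence_iterations == 0:
        state.redraw_motility(params)
    vel = _passive_velocities(state, params, log_collisions=log_collisions)
    tip_force = float(vel[tip_indices, 0].sum()) if tip_indices is not None else None
    vel = vel + params.motility_magnitude[state.types][:, None] * state.motility_vectors
    if not np.isfinite(vel).all():
        bad = state.ids[~np.isfinite(vel).any(axis=1)]
        raise FloatingPointError(f"non-finite velocity for cell ids {bad[:5]}")
    state.positions += vel * params.dt
    for wall in state.boundary.walls(state.dimension):
        d = wall.inward * (state.positions[:, wall.axis] - wall.coord)
        out = d < 0
        if out.any():
            state.positions[out, wall.axis] = wall.coord
            state.clamp_events += int(out.sum())
    state.iteration += 1
    return tip_force


def step(
    state: SimulationState,
    params: MechanicsParams,
    log_collisions: bool = True,
) -> SimulationState:
    """Advance one iteration in place (and return the state).

    Redraws motility directions when due, sums pairwise, wall and motility
    velocities, integrates with forward Euler, clamps any cell that crossed
    a rigid wall back onto it, and increments the iteration counter.
    """
    _step_impl(state, params, log_collisions, None)
    return state


def _axial_tip_indices(state, n_tip: int = 4) -> np.ndarray:
    """Indices of the n_tip posterior-most axial cells (AP ties by id)."""
    axial = np.flatnonzero(np.asarray(state.types) == TissueType.AXIAL.value)
    if len(axial) < n_tip:
        raise ValueError(f"need at least {n_tip} axial cells")
    x = np.asarray(state.positions)[axial, 0]
    ids = np.asarray(state.ids)[axial]
    order = np.lexsort((ids, x))
    return axial[order[-n_tip:]]


def add_influx(
    state: SimulationState,
    rate: float,
    rng: np.random.Generator | None = None,
    pd_length: float = 2.0,
    pd_half_width: float = 1.0,
    min_spacing: float = 0.4,
    max_tries: int = 10,
) -> SimulationState:
    """Add Poisson(rate) new PSM cells inside the current progenitor domain.

    New cells appear at random positions in the rear half of the midline
    progenitor domain (progenitors ingress from the tailbud side, away from
    the advancing axial tip); insertions
    that cannot respect ``min_spacing`` after ``max_tries`` draws are
    skipped and counted.  ``rate`` = 0 reproduces the no-influx condition.
    """
    if rate < 0:
        raise ValueError("influx rate must be non-negative")
    rng = rng or state.rng
    n_new = int(rng.poisson(rate))
    if n_new == 0:
        return state
    axial = state.types == TissueType.AXIAL.value
    ax_end = state.positions[axial, 0].max()
    tree = cKDTree(state.positions)
    new_pos = []
    for _ in range(n_new):
        placed = False
        for _ in range(max_tries):
            p = np.empty(state.dimension)
            p[0] = rng.uniform(ax_end + 0.5 * pd_length, ax_end + pd_length)
            p[1] = rng.uniform(-pd_half_width, pd_half_width)
            if state.dimension == 3:
                p[2] = rng.uniform(-pd_half_width, pd_half_width)
            d, _idx = tree.query(p, k=1)
            if d >= min_spacing and all(
                w.inward * (p[w.axis] - w.coord) > 0
                for w in state.boundary.walls(state.dimension)
            ):
                new_pos.append(p)
                placed = True
                break
        if not placed:
            state.influx_skipped += 1
    if not new_pos:
        return state
    k = len(new_pos)
    new_pos = np.asarray(new_pos)
    psm = TissueType.PSM.value
    state.positions = np.vstack([state.positions, new_pos])
    state.types = np.concatenate([state.types, np.full(k, psm, dtype=np.int8)])
    state.ids = np.concatenate(
        [state.ids, np.arange(state.next_id, state.next_id + k, dtype=np.int64)]
    )
    state.next_id += k
    state.radii = np.concatenate([state.radii, np.full(k, CELL_RADIUS)])
    state.adhesion_distances = np.concatenate(
        [state.adhesion_distances, np.full(k, CELL_RADIUS * TYPE_ADHESION_MULT[psm])]
    )
    if state.dimension == 2:
        ang = rng.uniform(0, 2 * np.pi, size=k)
        dirs = np.column_stack([np.cos(ang), np.sin(ang)])
    else:
        v = rng.normal(size=(k, 3))
        dirs = v / np.linalg.norm(v, axis=1, keepdims=True)
    state.motility_vectors = np.vstack([state.motility_vectors, dirs])
    return state


@dataclass
class Trajectory:
    """Recorded output of one simulation run."""

    snapshots: list[Snapshot]
    iterations: np.ndarray  # per-iteration axis of the scalar logs
    axis_lengths: np.ndarray
    cell_counts: np.ndarray
    axial_force: np.ndarray | None  # AP force sum on the 4 posterior-most axial cells
    collisions: np.ndarray
    params: MechanicsParams
    seed: int
    record_every: int
    perturbation: object | None = None
    perturbation_iteration: int | None = None
    perturbation_snapshot_index: int | None = None
    final_state: SimulationState | None = None

    @property
    def n_iterations(self) -> int:
        return int(self.iterations[-1]) if len(self.iterations) else 0

    def write_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["seed"] = self.seed
            f.attrs["record_every"] = self.record_every
            f.attrs["dt"] = self.params.dt
            f.create_dataset("iterations", data=self.iterations)
            f.create_dataset("axis_lengths", data=self.axis_lengths)
            f.create_dataset("cell_counts", data=self.cell_counts)
            if self.axial_force is not None:
                f.create_dataset("axial_force", data=self.axial_force)
            snaps = f.create_group("snapshots")
            for s in self.snapshots:
                g = snaps.create_group(f"iter_{s.iteration:07d}")
                g.create_dataset("ids", data=s.ids)
                g.create_dataset("positions", data=s.positions)
                g.create_dataset("types", data=s.types)

    @classmethod
    def read_hdf5(cls, path) -> "Trajectory":
        """Load the recorded snapshots and scalar logs (collision records
        are not serialized; pressure readouts need in-memory trajectories)."""
        import h5py

        with h5py.File(path, "r") as f:
            snapshots = []
            for key in sorted(f["snapshots"]):
                g = f["snapshots"][key]
                snapshots.append(
                    Snapshot(
                        iteration=int(key.split("_")[1]),
                        ids=g["ids"][...],
                        positions=g["positions"][...],
                        types=g["types"][...],
                    )
                )
            force = f["axial_force"][...] if "axial_force" in f else None
            return cls(
                snapshots=snapshots,
                iterations=f["iterations"][...],
                axis_lengths=f["axis_lengths"][...],
                cell_counts=f["cell_counts"][...],
                axial_force=force,
                collisions=np.empty(0, dtype=_COLLISION_DTYPE),
                params=MechanicsParams(dt=float(f.attrs["dt"])),
                seed=int(f.attrs["seed"]),
                record_every=int(f.attrs["record_every"]),
            )


def run(
    construct: TissueConstruct,
    params: MechanicsParams | None = None,
    n_iterations: int = 2000,
    influx_rate: float = 0.0,
    perturbation=None,
    record_every: int = 50,
    seed: int = 0,
    log_collisions: bool = True,
    record_forces: bool = True,
) -> Trajectory:
    """Full simulation loop.

    Runs ``n_iterations`` explicit-Euler iterations from the construct,
    optionally adding progenitor influx every iteration and applying one
    perturbation at its configured iteration (a snapshot is recorded
    immediately after application).  Snapshots are recorded every
    ``record_every`` iterations plus the initial and final states; axis
    length, cell count and (optionally) the AP force on the axial tip are
    logged every iteration.  Identical arguments and seed give bit-identical
    trajectories.
    """
    from . import perturb as _perturb

    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    params = params or MechanicsParams()
    state = SimulationState.from_construct(construct, seed=seed)
    snapshots = [state.snapshot()]
    iters = np.arange(n_iterations, dtype=np.int64)
    lengths = np.empty(n_iterations)
    counts = np.empty(n_iterations, dtype=np.int64)
    forces = np.empty(n_iterations) if record_forces else None
    anterior = 0.0
    perturb_iter = None
    perturb_snap_idx = None
    current_influx = influx_rate

    for t in range(n_iterations):
        if perturbation is not None and state.iteration == perturbation.apply_at_iteration:
            if perturbation.kind == "SET_INFLUX":
                current_influx = perturbation.influx_rate
                _perturb.apply(state, perturbation)
            else:
                _perturb.apply(state, perturbation)
            perturb_iter = state.iteration
            snapshots.append(state.snapshot())
            perturb_snap_idx = len(snapshots) - 1
        if current_influx > 0:
            add_influx(state, current_influx)
        # In the overdamped model the pre-integration interaction velocities
        # double as forces; the axial-tip AP sum is the pushing-force readout.
        tip = _axial_tip_indices(state) if record_forces else None
        tip_force = _step_impl(state, params, log_collisions, tip)
        if record_forces:
            forces[t] = tip_force
        ax = np.flatnonzero(state.types == TissueType.AXIAL.value)
        x = state.positions[ax, 0]
        tip4 = np.partition(x, len(x) - 4)[-4:] if len(x) >= 4 else x
        lengths[t] = tip4.mean() - anterior
        counts[t] = state.n_cells
        if state.iteration % record_every == 0:
            snapshots.append(state.snapshot())

    if snapshots[-1].iteration != state.iteration:
        snapshots.append(state.snapshot())
    return Trajectory(
        snapshots=snapshots,
        iterations=iters + 1,
        axis_lengths=lengths,
        cell_counts=counts,
        axial_force=forces,
        collisions=state.collision_array(),
        params=params,
        seed=seed,
        record_every=record_every,
        perturbation=perturbation,
        perturbation_iteration=perturb_iter,
        perturbation_snapshot_index=perturb_snap_idx,
        final_state=state,
    )
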