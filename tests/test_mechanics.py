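"""Pairwise potentials, integrator, influx and run-level invariants."""

import numpy as np
import pytest

from elongsim.construct import BoundaryGeometry, TissueType, build_construct
from elongsim.mechanics import (
    MechanicsParams,
    SimulationState,
    add_influx,
    boundary_velocity,
    brute_force_velocities,
    motility_velocity,
    pair_velocity,
    run,
    stable_dt,
    step,
    _passive_velocities,
)
from elongsim.construct import pd_mask

from conftest import make_state, psm_cell


class TestPairVelocity:
    def test_zero_beyond_adhesion_range(self):
        a, b = psm_cell(0, [0, 0]), psm_cell(1, [2.0, 0])
        assert np.allclose(pair_velocity(a, b, MechanicsParams()), 0)

    def test_antisymmetric_for_identical_cells(self):
        p = MechanicsParams()
        a, b = psm_cell(0, [0, 0]), psm_cell(1, [0.7, 0.1])
        assert np.allclose(
            pair_velocity(a, b, p), -pair_velocity(b, a, p)
        )

    def test_overlap_repulsion_hand_value(self):
        # radius 0.5 each, c_ccr 10 both: magnitude 10 (1 - 0.8/1.0)^2 = 0.4
        p = MechanicsParams()
        a, b = psm_cell(0, [0, 0]), psm_cell(1, [0.8, 0.0])
        v = pair_velocity(a, b, p)
        assert np.allclose(v, [-0.4, 0.0])
        assert v[0] < 0  # pushed away from b

    def test_adhesion_pulls_within_band(self):
        p = MechanicsParams()
        a, b = psm_cell(0, [0, 0]), psm_cell(1, [1.1, 0.0])
        v = pair_velocity(a, b, p)
        mag = p.adhesion[1, 1] * (1 - 1.1 / 1.25) ** 2
        assert np.allclose(v, [mag, 0.0])  # toward b

    def test_coincident_cells_separate_deterministically(self):
        p = MechanicsParams()
        a, b = psm_cell(0, [1.0, 1.0]), psm_cell(1, [1.0, 1.0])
        v1 = pair_velocity(a, b, p, rng=np.random.default_rng(7))
        v2 = pair_velocity(a, b, p, rng=np.random.default_rng(7))
        assert np.allclose(v1, v2)
        assert np.linalg.norm(v1) > 0


class TestBoundaryVelocity:
    geometry = BoundaryGeometry(field_length=15, half_width=5)

    def test_far_from_walls_is_zero(self):
        cell = psm_cell(0, [7.0, 0.0])
        v, rec = boundary_velocity(cell, self.geometry, MechanicsParams())
        assert np.allclose(v, 0) and rec == []

    def test_left_wall_pushes_toward_midline(self):
        cell = psm_cell(0, [7.0, -4.9])
        v, rec = boundary_velocity(cell, self.geometry, MechanicsParams())
        assert v[1] > 0 and len(rec) == 1

    def test_impulse_hand_value(self):
        # d = 0.25, radius 0.5, coefficient 10: 10 (1 - 0.25/0.5)^2 = 2.5
        cell = psm_cell(0, [0.25, 0.0])
        _, rec = boundary_velocity(cell, self.geometry, MechanicsParams())
        (name, ap, mag), = rec
        assert name == "anterior" and mag == pytest.approx(2.5)


class TestMotility:
    def test_axial_cells_have_zero_motility(self):
        from elongsim.construct import CellRecord

        cell = CellRecord(id=0, position=np.zeros(2),
                          tissue_type=TissueType.AXIAL)
        assert np.allclose(motility_velocity(cell, MechanicsParams()), 0)

    def test_psm_speed_is_table_value(self):
        cell = psm_cell(0, [0, 0], motility_vector=np.array([0.0, 1.0]))
        v = motility_velocity(cell, MechanicsParams())
        assert np.linalg.norm(v) == pytest.approx(1.2)

    def test_redrawn_directions_average_to_zero(self):
        state = make_state([[5.0, 0.0]] * 1, [TissueType.PSM])
        params = MechanicsParams()
        acc = np.zeros(2)
        for _ in range(10_000):
            state.redraw_motility(params)
            acc += state.motility_vectors[0]
        assert np.linalg.norm(acc / 10_000) < 0.03


class TestStep:
    def test_frozen_params_leave_positions_unchanged(self, zero_params):
        state = make_state([[3.0, 0.0], [3.4, 0.2]], [1, 1])
        before = state.positions.copy()
        step(state, zero_params)
        assert np.array_equal(state.positions, before)
        assert state.iteration == 1

    def test_free_cell_moves_exactly_by_motility(self, zero_params):
        params = MechanicsParams(
            repulsion=np.zeros((3, 3)),
            adhesion=np.zeros((3, 3)),
            boundary_repulsion=0.0,
        )
        state = make_state([[5.0, 0.0]], [TissueType.PSM])
        state.iteration = 1  # skip the scheduled redraw at iteration 0
        m = np.array([0.6, 0.8])
        state.motility_vectors[0] = m
        step(state, params)
        assert np.allclose(
            state.positions[0], [5.0, 0.0] + 1.2 * m * params.dt
        )

    def test_pair_displacements_antisymmetric(self):
        params = MechanicsParams(
            motility_magnitude=np.zeros(3), boundary_repulsion=0.0
        )
        state = make_state([[5.0, 0.0], [5.8, 0.0]], [1, 1])
        before = state.positions.copy()
        step(state, params)
        d = state.positions - before
        assert np.allclose(d[0], -d[1])

    def test_engine_matches_brute_force_oracle(self):
        cons = build_construct(
            dimension=2, counts={"AXIAL": 10, "PSM": 30, "POSTERIOR": 10},
            seed=5,
        )
        state = SimulationState.from_construct(cons, seed=5)
        params = MechanicsParams()
        fast = _passive_velocities(state, params, log_collisions=False)
        slow = brute_force_velocities(state, params)
        scale = np.abs(slow).max()
        assert np.allclose(fast, slow, rtol=1e-10, atol=1e-10 * scale)


class TestInflux:
    def _empty_pd_state(self):
        # four axial cells on the midline, lots of free posterior space
        pos = [[x, 0.0] for x in (1.0, 2.0, 3.0, 4.0)]
        return make_state(pos, [TissueType.AXIAL] * 4, half_width=5.0)

    def test_rate_zero_is_identity(self):
        state = self._empty_pd_state()
        for _ in range(100):
            add_influx(state, 0.0)
        assert state.n_cells == 4

    def test_poisson_counts_within_three_sigma(self):
        state = self._empty_pd_state()
        rng = np.random.default_rng(11)
        draws = 2000
        for _ in range(draws):
            add_influx(state, 0.5, rng=rng)
        total = (state.n_cells - 4) + state.influx_skipped
        assert abs(total - 1000) < 3 * np.sqrt(1000)

    def test_new_cells_are_psm_inside_pd(self):
        state = self._empty_pd_state()
        rng = np.random.default_rng(3)
        while state.n_cells < 8:
            add_influx(state, 1.0, rng=rng)
        new = state.ids >= 4
        assert (state.types[new] == TissueType.PSM.value).all()
        mask = pd_mask(state)
        assert set(state.ids[new]) <= mask


class TestRun:
    def test_identical_seeds_give_identical_trajectories(self):
        cons = build_construct(dimension=2, seed=9)
        t1 = run(cons, n_iterations=50, influx_rate=0.1, seed=9)
        t2 = run(cons, n_iterations=50, influx_rate=0.1, seed=9)
        assert np.array_equal(
            t1.snapshots[-1].positions, t2.snapshots[-1].positions
        )
        assert np.array_equal(t1.axis_lengths, t2.axis_lengths)

    def test_cell_count_conserved_without_influx(self):
        cons = build_construct(dimension=2, seed=2)
        traj = run(cons, n_iterations=100, influx_rate=0.0, seed=2)
        assert (traj.cell_counts == cons.n_cells).all()

    def test_confinement_holds_throughout(self):
        cons = build_construct(dimension=2, seed=4)
        traj = run(cons, n_iterations=200, seed=4)
        pos = traj.snapshots[-1].positions
        for wall in cons.boundary.walls(2):
            d = wall.inward * (pos[:, wall.axis] - wall.coord)
            assert (d >= -1e-9).all()

    def test_axial_tissue_expands_over_seeds(self):
        # confined motile pPSM drives axial AP expansion
        from elongsim.recipes import standard_params

        gained = []
        for seed in range(10):
            cons = build_construct(dimension=2, seed=seed)
            ax0 = cons.positions[cons.types == TissueType.AXIAL.value, 0]
            traj = run(cons, standard_params(), n_iterations=2000, seed=seed,
                       log_collisions=False, record_forces=False)
            s = traj.snapshots[-1]
            ax1 = s.positions[s.types == TissueType.AXIAL.value, 0]
            gained.append((ax1.max() - ax1.min()) - (ax0.max() - ax0.min()))
        assert np.mean(gained) > 0

    def test_stable_dt_decreases_with_stiffness(self):
        assert stable_dt(max_coefficient=80.0) < stable_dt(max_coefficient=10.0)
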