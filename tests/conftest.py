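import numpy as np
import pytest

from elongsim.construct import (
    BoundaryGeometry,
    CellRecord,
    TissueConstruct,
    TissueType,
    build_construct,
)
from elongsim.mechanics import MechanicsParams, SimulationState


@pytest.fixture
def default_construct():
    return build_construct(dimension=2, seed=0)


@pytest.fixture
def zero_params():
    """Parameters that freeze all dynamics (identity integrator)."""
    return MechanicsParams(
        repulsion=np.zeros((3, 3)),
        adhesion=np.zeros((3, 3)),
        motility_magnitude=np.zeros(3),
        boundary_repulsion=0.0,
    )


def make_state(positions, types, half_width=50.0, field_length=100.0, seed=0):
    """Hand-built simulation state from raw position/type lists."""
    positions = np.asarray(positions, dtype=float)
    types = np.asarray(types, dtype=np.int8)
    radii = np.full(len(positions), 0.5)
    mult = np.array([1.1, 1.25, 1.1])
    return SimulationState(
        positions=positions.copy(),
        types=types,
        ids=np.arange(len(positions), dtype=np.int64),
        radii=radii,
        adhesion_distances=radii * mult[types],
        motility_vectors=np.zeros_like(positions),
        boundary=BoundaryGeometry(field_length=field_length, half_width=half_width),
        rng=np.random.default_rng(seed),
        next_id=len(positions),
    )


def psm_cell(cid, pos, **kw):
    return CellRecord(id=cid, position=np.asarray(pos, float),
                      tissue_type=TissueType.PSM, **kw)
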