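"""YAML (de)serialization of run configuration.

One schema covers construct geometry, mechanics parameters and perturbation
specs so that a run is fully reproducible from its config file plus seed.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .construct import BoundaryGeometry, LayoutSpec
from .mechanics import MechanicsParams
from .perturb import PerturbationSpec

__all__ = ["params_to_dict", "params_from_dict", "save_config", "load_config"]


def params_to_dict(params: MechanicsParams) -> dict:
    return {
        "repulsion": np.asarray(params.repulsion).tolist(),
        "adhesion": np.asarray(params.adhesion).tolist(),
        "motility_magnitude": np.asarray(params.motility_magnitude).tolist(),
        "adhesion_distance_multiplier": np.asarray(
            params.adhesion_distance_multiplier
        ).tolist(),
        "boundary_repulsion": params.boundary_repulsion,
        "boundary_adhesion": params.boundary_adhesion,
        "dt": params.dt,
        "motility_persistence": params.motility_persistence,
    }


def params_from_dict(d: dict) -> MechanicsParams:
    return MechanicsParams(**d)


def save_config(
    path: str | Path,
    params: MechanicsParams | None = None,
    geometry: BoundaryGeometry | None = None,
    layout: LayoutSpec | None = None,
    perturbation: PerturbationSpec | None = None,
    **extra,
) -> None:
    cfg: dict = dict(extra)
    if params is not None:
        cfg["mechanics"] = params_to_dict(params)
    if geometry is not None:
        cfg["geometry"] = asdict(geometry)
    if layout is not None:
        cfg["layout"] = asdict(layout)
    if perturbation is not None:
        cfg["perturbation"] = asdict(perturbation)
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    out = dict(cfg)
    if "mechanics" in cfg:
        out["mechanics"] = params_from_dict(cfg["mechanics"])
    if "geometry" in cfg:
        out["geometry"] = BoundaryGeometry(**cfg["geometry"])
    if "layout" in cfg:
        out["layout"] = LayoutSpec(**cfg["layout"])
    if "perturbation" in cfg:
        out["perturbation"] = PerturbationSpec(**cfg["perturbation"])
    return out
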