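"""Reproducible in-silico experiment recipes.

Each recipe fully determines a batch of simulations (construct, mechanics
parameters, perturbations, replicate seeds) and the readout tables it
emits.  All randomness flows from one root seed via per-run derivation, so
rerunning a recipe with the same manifest reproduces its tables exactly.

Recipes
-------
influx_feedback
    Elongation progress and PSM grid density with the progenitor influx on
    vs off: the negative-feedback role of cell addition.
perturbation_readouts
    Boundary pressure along AP, axial pushing force and PD lateral flux
    after graded pulling, graded compression, or pPSM cell deletion,
    against unperturbed controls.
length_recovery
    Axis length trajectories and elongation extents after global stretch or
    compression, to test whether the axis returns to the control length.
repulsion_sweep
    One-parameter slice of PSM-PSM repulsion (no influx) with regime
    classification and transition detection.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import measure, sweep as sweep_mod
from .construct import build_construct
from .mechanics import MechanicsParams, run
from .perturb import PerturbationSpec
from .sweep import _derive_seed

__all__ = ["ExperimentRecipe", "RECIPES", "run_recipe"]

#: Default progenitor influx rate (new PSM cells per iteration) sustaining
#: a stable pPSM density in the standard 2D field.
DEFAULT_INFLUX_RATE = 0.02

#: Standard 2D mechanics: homotypic coefficients from the parameter table,
#: heterotypic PSM-axial and PSM-posterior repulsion at the midpoints of the
#: documented exploration ranges (50 and 35) so the tissues stay segregated.
def standard_params() -> MechanicsParams:
    return MechanicsParams.with_repulsion(psm_nc=50.0, psm_post=35.0)


@dataclass
class ExperimentRecipe:
    """A named, fully seeded batch of simulations plus readouts."""

    name: str
    description: str
    conditions: dict  # condition name -> dict of run() overrides
    n_iterations: int = 3000
    replicates: int = 20
    readouts: tuple[str, ...] = ("length",)
    construct_kwargs: dict = field(default_factory=dict)

    @property
    def run_flags(self) -> dict:
        # only log what the recipe's readouts consume
        return {
            "log_collisions": "pressure" in self.readouts,
            "record_forces": "force" in self.readouts,
        }

    def config(self, overrides: dict | None = None) -> dict:
        cfg = {
            "name": self.name,
            "n_iterations": self.n_iterations,
            "replicates": self.replicates,
            "conditions": {
                k: {kk: _jsonable(vv) for kk, vv in v.items()}
                for k, v in self.conditions.items()
            },
            "readouts": list(self.readouts),
            "construct_kwargs": dict(self.construct_kwargs),
        }
        if overrides:
            cfg.update({k: _jsonable(v) for k, v in overrides.items()})
        return cfg


def _jsonable(v):
    if isinstance(v, PerturbationSpec):
        return asdict(v)
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    return v


def _std_perturb(kind: str, strain: float, at: int) -> PerturbationSpec:
    return PerturbationSpec(kind=kind, strain=strain, apply_at_iteration=at)


RECIPES: dict[str, ExperimentRecipe] = {
    "influx_feedback": ExperimentRecipe(
        name="influx_feedback",
        description="elongation and pPSM density with influx on vs off",
        conditions={
            "influx_on": {"influx_rate": DEFAULT_INFLUX_RATE},
            "influx_off": {"influx_rate": 0.0},
        },
        n_iterations=6000,
        replicates=20,
        readouts=("length", "density"),
    ),
    "perturbation_readouts": ExperimentRecipe(
        name="perturbation_readouts",
        description="pressure/force/flux after graded strain or deletion",
        conditions={
            "control": {"influx_rate": DEFAULT_INFLUX_RATE},
            "pulled": {
                "influx_rate": DEFAULT_INFLUX_RATE,
                "perturbation": PerturbationSpec(
                    kind="GRADED_STRAIN", strain=+0.12, apply_at_iteration=1000
                ),
            },
            "compressed": {
                "influx_rate": DEFAULT_INFLUX_RATE,
                "perturbation": PerturbationSpec(
                    kind="GRADED_STRAIN", strain=-0.12, apply_at_iteration=1000
                ),
            },
            "deleted": {
                "influx_rate": DEFAULT_INFLUX_RATE,
                "perturbation": PerturbationSpec(
                    kind="DELETE_PPSM", deletion_fraction=0.5,
                    apply_at_iteration=1000,
                ),
            },
        },
        n_iterations=3000,
        replicates=10,
        readouts=("pressure", "force", "flux"),
    ),
    "length_recovery": ExperimentRecipe(
        name="length_recovery",
        description="axis length recovery after global stretch/compression",
        conditions={
            "control": {"influx_rate": DEFAULT_INFLUX_RATE},
            "stretched": {
                "influx_rate": DEFAULT_INFLUX_RATE,
                "perturbation": _std_perturb("GLOBAL_STRAIN", +0.12, 1000),
            },
            "compressed": {
                "influx_rate": DEFAULT_INFLUX_RATE,
                "perturbation": _std_perturb("GLOBAL_STRAIN", -0.12, 1000),
            },
        },
        n_iterations=6000,
        replicates=40,
        readouts=("length", "extent"),
    ),
    "repulsion_sweep": ExperimentRecipe(
        name="repulsion_sweep",
        description="PSM-PSM repulsion slice, regime transition (no influx)",
        conditions={"slice": {}},
        n_iterations=2000,
        replicates=5,
        readouts=("sweep",),
    ),
}


def _run_condition(recipe, cond_name, cond, n_iter, replicates, seed):
    trajs, seeds, failed = [], [], []
    for rep in range(replicates):
        run_seed = _derive_seed(seed, zlib.crc32(cond_name.encode()) % 10000, rep)
        seeds.append(run_seed)
        try:
            cons = build_construct(dimension=2, seed=run_seed,
                                   **recipe.construct_kwargs)
            trajs.append(
                run(
                    cons,
                    standard_params(),
                    n_iterations=n_iter,
                    record_every=200,
                    seed=run_seed,
                    **recipe.run_flags,
                    **cond,
                )
            )
        except Exception:
            failed.append(run_seed)
    return trajs, seeds, failed


def run_recipe(
    name: str,
    overrides: dict | None = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
) -> dict:
    """Execute a recipe and return (and optionally write) its result bundle.

    The bundle holds per-condition trajectories, readout tables, and a
    provenance manifest (package version, config hash, per-run seeds).
    Partial failures mark the bundle incomplete and list the failed seeds.
    """
    if name not in RECIPES:
        raise KeyError(f"unknown recipe {name!r}; available: {sorted(RECIPES)}")
    recipe = RECIPES[name]
    overrides = overrides or {}
    n_iter = int(overrides.get("n_iterations", recipe.n_iterations))
    replicates = int(overrides.get("replicates", recipe.replicates))
    cfg = recipe.config({**overrides, "seed": seed})
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    bundle: dict = {"name": name, "tables": {}, "trajectories": {}}
    manifest = {
        "recipe": name,
        "version": __version__,
        "config": cfg,
        "config_hash": cfg_hash,
        "seeds": {},
        "failed_seeds": {},
        "complete": True,
    }

    if name == "repulsion_sweep":
        points = sweep_mod.generate_grid(mode="one_axis_slice", axis="psm_psm",
                                         points=overrides.get("points", 17))
        df = sweep_mod.run_sweep(
            points, n_iterations=n_iter, replicates=replicates, seed=seed
        )
        agg = sweep_mod.aggregate_sweep(df)
        bundle["tables"]["sweep"] = df
        bundle["tables"]["sweep_aggregated"] = agg
        try:
            tr = sweep_mod.find_transition(agg)
            bundle["transition"] = tr
            manifest["transition_scaled"] = tr.scaled_value
        except ValueError:
            manifest["complete"] = False
        manifest["seeds"] = {"slice": df["seed"].tolist()}
    else:
        for cond_name, cond in recipe.conditions.items():
            trajs, seeds, failed = _run_condition(
                recipe, cond_name, cond, n_iter, replicates, seed
            )
            bundle["trajectories"][cond_name] = trajs
            manifest["seeds"][cond_name] = seeds
            if failed:
                manifest["failed_seeds"][cond_name] = failed
                manifest["complete"] = False
        bundle["tables"].update(_tables_for(recipe, bundle["trajectories"]))

    bundle["manifest"] = manifest
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for tname, table in bundle["tables"].items():
            df = table if isinstance(table, pd.DataFrame) else table.to_frame()
            df.to_csv(out / f"{name}_{tname}.csv", index=False)
        with open(out / f"{name}_manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, default=str)
    return bundle


def _tables_for(recipe, trajectories) -> dict:
    tables: dict = {}
    for cond, trajs in trajectories.items():
        if not trajs:
            continue
        if "length" in recipe.readouts:
            lengths = np.vstack([t.axis_lengths for t in trajs])
            keep = slice(9, None, 10)  # every 10th iteration keeps tables small
            tables[f"length_{cond}"] = pd.DataFrame(
                {
                    "iteration": trajs[0].iterations[keep],
                    "mean": lengths.mean(axis=0)[keep],
                    "sd": lengths.std(axis=0)[keep],
                    "n": len(trajs),
                }
            )
        if "density" in recipe.readouts:
            profs = [measure.density_profile(t.snapshots[-1], max_distance=10.0)
                     for t in trajs]
            stack = np.vstack([p.values for p in profs])
            tables[f"density_{cond}"] = pd.DataFrame(
                {
                    "distance": profs[0].bin_centers,
                    "label": profs[0].labels,
                    "mean": np.nanmean(stack, axis=0),
                    "sd": np.nanstd(stack, axis=0),
                    "n": len(trajs),
                }
            )
        if "pressure" in recipe.readouts:
            tables[f"pressure_{cond}"] = measure.boundary_pressure(trajs).to_frame()
        if "force" in recipe.readouts:
            tables[f"force_{cond}"] = measure.axial_push_force(trajs).to_frame()
        if "flux" in recipe.readouts:
            tables[f"flux_{cond}"] = measure.pd_lateral_flux(trajs).to_frame()
        if "extent" in recipe.readouts:
            tables[f"extent_{cond}"] = pd.DataFrame(
                {"extent": [measure.elongation_extent(t) for t in trajs]}
            )
    return tables
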