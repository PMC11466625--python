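# elongsim

An agent-based, multi-tissue model of vertebrate body-axis elongation, for
researchers studying the tissue mechanics of posterior trunk formation.

During trunk elongation, the posterior presomitic mesoderm (pPSM) — a
low-density mesenchymal tissue flanking the notochord and neural tube —
expands and, because it is confined laterally and anteriorly, pushes the
passive axial tissues posteriorly.  New PSM cells enter from a progenitor
domain (PD) on the posterior midline, closing a feedback loop in which
pPSM cell density couples progenitor influx, tissue pressure and
elongation speed.  `elongsim` implements this system as an overdamped
center-based model: each cell i of radius R_i moves with velocity

    v_i = Σ_j [ c_r (1 − d_ij/(R_i+R_j))² û_ji  −  c_a (1 − d_ij/(R_iA+R_jA))² û_ij ]
          + f_wall(x_i) + v_mot,i

(quadratic-falloff repulsion inside contact, weak adhesion out to the
adhesion distance R_iA, rigid-wall repulsion, and a random-direction
motility term for PSM cells).  The package provides

- `elongsim.construct` — synthetic initial conditions: jittered-lattice
  multi-tissue layouts in 2D (375 cells) and 3D (7920 cells);
- `elongsim.mechanics` — the simulator core with neighbor-list forces,
  progenitor influx and full trajectory logging;
- `elongsim.perturb` — in-silico pulling, compression (global or
  exponentially graded along AP) and pPSM cell deletion;
- `elongsim.measure` — axis length, elongation extent, grid density
  profiles, boundary pressure along AP, axial pushing force, PD lateral
  flux, and convergence/elongation regime classification;
- `elongsim.sweep` — parameter sweeps over the five cell-cell repulsion
  coefficients, transition-boundary detection and a shallow-network
  surrogate of sweep outputs;
- `elongsim.recipes` + a CLI (`elongsim build|run|sweep|surrogate|recipe`)
  for fully seeded, manifest-backed experiment batches.

See `docs/methods.md` for the model, parameters and limitations.

## Worked example

Locate the collective-movement regime transition along the PSM-PSM
repulsion axis (all other repulsions at their range midpoints, no influx):

```python
from elongsim import sweep as sw

points = sw.generate_grid(mode="one_axis_slice", axis="psm_psm", points=17)
df = sw.run_sweep(points, n_iterations=2000, replicates=5, seed=1)
agg = sw.aggregate_sweep(df)
print(agg[["scaled_psm_psm", "ratio", "label"]].tail(3).to_string(index=False))
tr = sw.find_transition(agg)
print(f"transition at scaled {tr.scaled_value:.3f} (raw {tr.raw_value:.1f})")
```

prints (about two minutes on one CPU):

```
 scaled_psm_psm    ratio      label
         0.8750 1.262843 ELONGATION
         0.9375 1.305756 ELONGATION
         1.0000 1.326726 ELONGATION
transition at scaled 0.562 (raw 27.5)
```

`ratio` is the elongation/convergence dominance of the displacement field:
below 1 the run is convergence-dominated (weakly repulsive PSM rearranges
laterally), above 1 elongation-dominated (strongly repulsive PSM drives
posterior flow).  The transition sits mid-range: PSM-PSM repulsion — the
model's stand-in for pPSM cell activity — is the determinant parameter.

The numbered drivers under `analysis/` run the full in-silico experiments
(constructs, influx feedback, perturbation readouts, length recovery,
sweep, surrogate) and write tidy tables under `results/`:

```sh
python analysis/01_build_constructs.py
python analysis/05_sweep_transition.py --seed 1
python analysis/06_surrogate.py
```

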