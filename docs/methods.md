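# Model and methods

## The model

`elongsim` implements an overdamped, center-based agent model of the
posterior body axis of an elongating vertebrate embryo.  Three tissues are
represented as collections of spherical cells of radius 0.5 (one diameter =
one model length unit):

- **Axial tissue** (notochord and neural tube merged into one passive
  column) on the midline;
- **Presomitic mesoderm (PSM)**, motile mesenchymal cells flanking the
  axial column bilaterally, with a **progenitor domain (PD)** of PSM-type
  cells on the midline just posterior to the axial tip;
- **Posterior cells**, a passive cap occupying the posterior end of the
  field.

The field is confined by rigid anterior and lateral walls (plus
dorsal/ventral walls in 3D); the posterior end is open, so all elongation
happens by posterior displacement of material.

In the overdamped limit, inertia is negligible and each cell's velocity is
set directly by its interactions:

    v_i = Σ_j f_ij  +  f_wall(x_i)  +  v_mot,i
    x_i ← x_i + v_i Δt                      (forward Euler)

Pairwise interactions use quadratic-falloff potentials.  With center
distance d, radii R_i, R_j and maximum adhesion distances R_iA, R_jA:

- repulsion for d < R_i + R_j, magnitude c_r (1 − d/(R_i+R_j))², pushing
  apart;
- adhesion for R_i + R_j ≤ d < R_iA + R_jA, magnitude
  c_a (1 − d/(R_iA+R_jA))², pulling together;
- nothing beyond the adhesion range.

Walls repel with the same falloff once a cell's center is within one radius
of the plane; every wall contact is logged (wall, AP position, impulse) for
the pressure readout.  Motile cells carry an active velocity of fixed
magnitude whose direction is redrawn uniformly at random ("directionless"
motility) every persistence interval.  There is no cell cycle, apoptosis,
chemical signaling, or active intercalation; cell count changes only
through explicit progenitor influx or deletion.

## Parameters

| parameter | AXIAL | PSM | POSTERIOR | notes |
|---|---|---|---|---|
| motility speed (length/time) | 0 | 1.2 | 0 | passive vs mesenchymal |
| relative adhesion c_a | 2.5 | 0.05 | 1 | homotypic |
| relative repulsion c_r | 10 | 10 | 10 | homotypic |
| adhesion distance (× radius) | 1.1 | 1.25 | 1.1 | sets R_iA |

Heterotypic coefficients default to the geometric mean of the homotypic
values.  The **standard 2D experiment set** (`recipes.standard_params`)
overrides the two tissue-interface repulsions to PSM–axial = 50 and
PSM–posterior = 35, the midpoints of the documented exploration ranges
(PSM–NC 20–80, PSM–posterior 10–60): with geometric-mean interfaces (10)
the motile PSM interdigitates with the passive column and disperses it
within a few thousand iterations (axial half-width grows from 1 to > 4),
whereas the documented interface strengths keep the tissues segregated, as
a real notochord boundary does.

Other defaults:

- **Wall repulsion coefficient** 10, range one radius.  Wall adhesion is
  implemented but defaults to 0 (per-run values for it are undocumented;
  confinement alone reproduces the target behaviors).
- **Time step** Δt = 0.005 for default coefficients.  `stable_dt` derives
  the step from a maximum-displacement rule: the largest plausible
  per-iteration displacement (three simultaneous contacts at 40% relative
  overlap at the stiffest coefficient in play, plus motility) must stay
  below 10% of a radius.  Sweeps, whose interface coefficients reach 80,
  therefore integrate with Δt ≈ 0.00126.
- **Motility persistence** 1.0 time units.  Persistence is specified in
  model time, not iterations, because a per-iteration redraw would tie the
  effective diffusivity (D = v²τ/2 ≈ 0.72 length²/time at the defaults) to
  the integration step: halving Δt would halve the random-walk diffusion,
  changing the physics under pure time-step refinement.
- **Progenitor influx** 0.02 cells/iteration (Poisson), inserted at random
  positions in the rear half of the PD with a minimum spacing of 0.4 to
  existing cells (insertions that cannot satisfy it after 10 draws are
  skipped and counted).  The rate is of the order of the material flux the
  elongating axis consumes (tip advance × PD cross-section × packing
  density); the published runs state no numeric rate.

## Initial condition (the synthetic-data stage)

Cells are placed on a jittered square lattice (jitter uniform ±10% of a
diameter per coordinate) at near-contact spacing 0.6 in 2D, giving 375
cells in the standard field: a field 15 long and 10 wide, an axial column 2
diameters wide reaching from the anterior wall to AP = 10, PSM flanks 4
diameters wide per side, a PD on the midline over AP 10–12, and a passive
cap over AP 12–15.  The sub-diameter spacing encodes the confluent,
compressed state of the posterior tissues: its stored pressure, together
with sustained cell motility, is the expansion potential that drives axis
elongation.  In 3D the same layout is extruded dorso-ventrally (half-depth
2) at spacing 0.38 and the PSM lattice is randomly trimmed so the default
field holds exactly 7920 cells.

The generator is a pure function of (dimension, counts, geometry, seed);
the left and right PSM blocks are mirror images up to jitter.  What it does
**not** emulate: the anterior–posterior cell-density gradient of the real
PSM (the lattice is uniform), anatomical substructure of the axial tissues,
extracellular matrix, and any chemical patterning.  Passing tests therefore
speak to the mechanical logic of confinement + motility + influx, not to
those features.

## Perturbations

- **Global strain**: every AP coordinate is rescaled by (1+s) about the
  anterior wall; ML/DV untouched.  Negative s is compression.
- **Graded strain**: cells in the posterior 75% (by AP rank) are displaced
  by A·exp((a − a_max)/λ); the amplitude A is chosen so the field's total
  AP strain equals the requested s exactly.  λ defaults to one third of the
  affected zone's extent — the exponential form concentrates displacement
  posteriorly, emulating probes acting on the posterior end; no published
  value for the constant exists, so it is exposed in the spec.  The map is
  monotone inside the affected zone; a small discontinuity at the
  zone boundary (the exponential tail, ≈ A·e⁻³) is accepted.
- **pPSM deletion**: removes a uniformly sampled fraction of PSM cells in
  the posterior 5 AP units up to the posterior-most axial cell, without
  replacement, deterministic under seed.
- Perturbations apply instantaneously between iterations; viscoelastic
  recoil of the embryo is not simulated.

## Readouts

- **Axis length**: mean AP position of the 4 posterior-most axial cells
  (ties broken by cell id), from the anterior wall.
- **Elongation extent**: final length over the length immediately after
  the perturbation (a dedicated snapshot is recorded at application time).
- **Grid density**: PSM cells counted in 1×1 grids, aggregated per 1-unit
  band of distance to the posterior axis end; bands within 5 units are
  labeled pPSM, the rest aPSM.
- **Boundary pressure**: wall-collision impulses of PSM cells summed into
  1-AP-unit bins, normalized per iteration.  Perturbation comparisons use
  the 500 iterations immediately after application, where the transient
  response lives.
- **Axial push force**: in an overdamped model the pre-integration
  interaction velocity *is* the force, so the recorded force on the axial
  tip is the summed AP interaction component (motility excluded) over the
  same 4-cell tip set, binned per 200 iterations.
- **PD lateral flux**: |ML displacement|/iteration of PD cells (PD
  membership recomputed per snapshot), binned per 200 iterations; empty
  bins are missing, not zero.  Absolute speeds are reported; a signed
  variant (positive = away from midline) is available.
- **Regime classification**: each PSM/axial cell's net displacement is
  decomposed into a *convergence* component — the magnitude of its ML
  displacement, motion along the convergence–extension axis of the
  bilaterally symmetric field — and an *elongation* component — its
  posterior AP displacement.  The run is labeled by whichever component's
  sum dominates (threshold ratio 1.0); the continuous ratio supports
  transition detection.  An earlier variant crediting only medially
  directed motion was evaluated and rejected: with rigid lateral walls and
  an open posterior end, clipped inward motion can never out-sum posterior
  drift anywhere in the explored parameter space, so that metric admits
  only one regime and cannot express the observed phase behavior.

## The parameter sweep and its surrogate

Sweeps run the 2D model without influx for 2000 iterations.  The five
repulsion coefficients are explored over PSM–PSM 5–45, NC–NC 1–16,
posterior–posterior 0.1–1.1, PSM–NC 20–80, PSM–posterior 10–60, min–max
scaled to [0, 1].  The default protocol is a one-axis slice (17 points × 5
replicate seeds) with the other parameters at range midpoints; a coarse
full grid (3⁵ points) is available.  The transition locator returns the
scaled midpoint between the highest convergence-labeled and lowest
elongation-labeled points (majority vote across replicates) and flags
non-monotone slices.  The surrogate is a one-hidden-layer (10 tanh units)
feed-forward regressor from the five scaled inputs to standardized axial
bounding-box length and width, trained with L-BFGS on a 70/15/15
train/validation/test split; validation selects the ridge penalty, and the
held-out R² on the test split is reported.

## Numerical choices

- Neighbor candidates come from a k-d tree queried at the maximum adhesion
  range; an O(N²) brute-force evaluation over per-pair reference functions
  is kept as an independent oracle and agrees to 1e-10 relative tolerance.
- Coincident cell centers (d < 1e-12) are separated along a random unit
  direction drawn from the run's seeded generator.
- A cell integrated past a rigid wall is clamped onto the wall plane and
  the event counted.
- All randomness flows from one root seed; batch runs derive per-run seeds
  via `numpy` SeedSequence spawning, so every recipe is bit-reproducible
  from its manifest.

## Problem sizes

The standard analyses use the 375-cell 2D field: sweeps run 2000
iterations per point; influx and recovery experiments 6000 iterations with
20–40 replicate seeds per condition; perturbation readouts 3000 iterations
with 10 seeds per group.  The 3D construct (7920 cells) is generated and
validated as an initial condition; long 3D runs are supported but not part
of the standard analyses.

## Known limitations

- **Influx vs tip advance.** Progenitor influx robustly sustains pPSM
  density (its removal lowers late-run pPSM density), but in this
  implementation inserted progenitors sit directly in the advancing axial
  tip's path and their back-pressure slows the tip more than the sustained
  density speeds it, for every insertion scheme and rate tried.  The
  density half of the influx feedback reproduces; the elongation half does
  not.  Related force/flux readouts after graded strain inherit the same
  physics: the immediate axial-force response is dominated by the
  displaced PD material in front of the tip rather than by the lateral
  pPSM squeeze, and PD lateral speeds are motility-noise-dominated at
  these cell numbers.
- The convergence regime relies on lateral rearrangement of a compressed
  field; there is no active convergent-extension term, so anterior
  convergence is weaker than in embryos.
- Tissue cohesion under the quadratic potentials is weak (the adhesive
  band contributes ≤ c_a·(1 − 1/1.1)² ≈ 0.008·c_a at contact), so tissue
  integrity over long runs depends on confinement and interface repulsion
  rather than adhesion.
- 2D runs are reported in iterations; 3D runs in virtual minutes with one
  iteration per minute.  No calibration to embryonic real time is implied.
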