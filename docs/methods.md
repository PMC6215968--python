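# Methods

## Model

`endocv` solves the bidomain equations of cardiac electrophysiology on a
two-dimensional cross-section of an atrial muscle strand, optionally
coupled to one or two passive conductive bath layers representing
intracavitary blood (endocardial side) and interstitial fluid
(epicardial side).  In the muscle region the transmembrane potential
V = V_i − V_e and the extracellular potential V_e satisfy

    div(D_i grad(V + V_e)) = chi (C_m dV/dt + I_ion) − I_i^v
    div(D_i grad V) + div((D_i + D_e) grad V_e) = I_total^v

and the bath potential satisfies Laplace's equation div(sigma_b grad V_b)
= 0.  The conductivity tensors are transversely isotropic about the local
fiber axis f: D = sigma_t I + (sigma_f − sigma_t) f⊗f.  Exterior
boundaries are insulated; on the muscle–bath interface the extracellular
and bath potentials and their normal currents are continuous and the
intracellular current vanishes.  Because of the interface continuity, the
extracellular and bath potentials are represented by a single nodal field
U on the whole mesh; the interface conditions are then natural conditions
of the weak form and require no explicit coupling terms.

Default physical parameters (mS/cm unless noted): sigma_i^f = sigma_e^f =
4.5, sigma_i^t = 0.45, sigma_e^t = 1.8, sigma_b = 20, C_m = 1 uF/cm²,
chi = 1000 cm⁻¹.  Unit system: mV, ms, cm, mS, uF, uA — the equations are
dimensionally consistent without conversion factors.

## Geometry

The strand is built straight — muscle [0, ℓm] × [−0.3, 2] cm, baths
attached left/right of it — and then bent.  The bend wraps the region
Y > 0 onto concentric circles centred at (−c·R₀, 0) with R₀ = Le/θ and
per-line radius R = R₀ + cX, which preserves the arc length of the
endocardial interface (X = 0) exactly for every bend angle.  The signed
interface curvature is κ = cθ/Le.  For c = +1 (positive curvature, the
left-atrial-posterior-wall-like case) the endocardial bath lies on the
inside of the bend, so injectivity requires ℓb < R₀; the muscle then sits
at radii larger than R₀, which is what slows the endocardial front.  The
strip Y ≤ 0 containing the stimulus is never deformed, so all curvatures
share identical initial conditions.  This construction is the unique
continuous, orientation-preserving map with these radii; a formulation
that differs from it by a mirror in x would represent the same physics.

The mesh is a structured triangulation (each hX × hY cell split along its
lower-left→upper-right diagonal) with hX = 25 um across the fiber and
hY = 50 um along it; a 25 um muscle is meshed with exactly one element
across, the strand's stand-in for a two-dimensional manifold model.  Bath
columns can optionally coarsen geometrically away from the interface
(three fine columns kept at hX as a boundary layer; conforming by
construction since only column widths change); the default is a uniform
grid, which is what all reported numbers use — the graded mesh reproduces
the uniform-bath CV within 1% at roughly half the node count (tested).  The
stimulus node set is the straight-frame predicate Y < −0.02797 cm, taken
verbatim from the study design (the odd value is presumably mesh-aligned;
reproducing it keeps the stimulated volume identical).

## Membrane kinetics

The default ionic model is the Courtemanche–Ramirez–Nattel human atrial
model (21 states), implemented from the 1998 publication with every
parameter exposed for configuration overlays.  The implementation is
checked against the quiescent state published with the model: the
resting gating values are reproduced to their printed precision,
and the equilibrated resting potential is −81.2 ± 0.5 mV.  Variant
parameter sets of this model exist (e.g. concentration-stabilised
descendants of the original code); with the published 1998 parameters the
planar conduction velocity at the default conductivities converges to
≈76.6 cm/s, a few percent above values reported for such variants, so
absolute CVs carry a corresponding systematic offset while all ratios,
orderings and relative effects are unaffected.  See the limitations
section.

A cubic bistable reaction I_ion = a(V − V_rest)(V − V_th)(V − V_peak) is
provided as a second membrane model.  Its rate constant is set in closed
form so that the continuum travelling-front speed c = sqrt(kD/2)(1 − 2α)
equals 0.07 cm/ms at the reference monodomain diffusivity
D = sigma_h/(chi C_m) (sigma_h the harmonic mean of the longitudinal
conductivities); defaults V_rest = −81.2 mV, V_peak = +20 mV, α = 0.2.
Because its wave speed has an exact closed form, this model doubles as an
independent verification of the tissue discretisation (the simulated
speed must match the formula within 5%).

## Discretisation

Linear (P1) triangular elements; piecewise-constant fibers and
conductivity tensors per element.  Time stepping is first-order IMEX:
the membrane states advance explicitly at each muscle node with the
membrane potential frozen at the old time level, then one sparse direct
solve advances (V, U) with diffusion implicit and chi·I_ion plus the
stimulus explicit on the right-hand side.  The factorisation (SuperLU) is
computed once per run and reused; at desk scale (< 2·10⁵ unknowns) this
replaces iterative preconditioned solvers without approximation.

Numerical choices that matter:

* **Mass lumping + nodal ionic currents (ICI).**  The time-derivative and
  ionic terms use the lumped mass matrix and the ionic current is
  evaluated at nodes.  This keeps the membrane update local and is
  standard for P1 cardiac FEM; it shifts CV at coarse meshes, which is
  why the mesh-convergence bound below is stated explicitly.
* **Gate integration.**  The fast Na activation gate has τ_m ≈ 8 us at
  rest, far below the production timestep (0.03125 ms), so plain forward
  Euler is outside its stability region there; it survives only through
  [0, 1] clipping and inflates CV by ≈4% relative to its own refined
  limit.  Gates therefore default to the Rush–Larsen exponential update
  (within 0.2% of the dt→0 limit at the production timestep); forward
  Euler remains available as a configuration option.  Concentrations
  always advance by forward Euler.
* **Timestep.**  dt is the largest negative power of two satisfying the
  CFL-style bound hX/v_X ≤ 1 with v_X = 0.08 cm/ms, giving dt = 0.03125
  ms at the production mesh; the bound is validated at run time.
* **Grounding.**  The pure-Neumann U-problem is singular up to an
  additive constant.  Default: a zero-mean constraint enforced by a
  symmetric rank-one bordering (Lagrange multiplier); a pin-one-node mode
  exists for cross-checking.  Bipolar electrograms are invariant to the
  choice to 10⁻⁸ mV (tested); unipolar traces differ by the constant.
* **Stimulus.**  Equal-and-opposite volumetric currents (I_e^v = +A,
  I_i^v = −A) confined to the tagged node set for 2 ms from t = 0, so the
  total applied current is zero and only the transmembrane equation sees
  a net source.  The default amplitude is A = chi × 100 uA/cm² of
  membrane = 10⁵ uA/cm³: a one-dimensional cable analysis shows that a
  volumetric amplitude of order 10² uA/cm³ changes V by well under 1 mV
  in 2 ms at chi·C_m = 10³ uF/cm³ and cannot initiate a wave, so the
  amplitude is interpreted as membrane-referenced.  The probes sit ≥ 1 cm
  from the stimulated strip; measured CVs are insensitive to stimulus
  details once the wave is launched.
* **Activation detection.**  Earliest upward crossing of −5 mV with
  linear sub-step interpolation (default on; without it the 0.03125 ms
  quantisation injects ≈0.5% CV error, comparable to the three-digit
  reported values).
* **CV estimators.**  Two-point: 0.5 cm of preserved interface arc length
  divided by the probe activation-time difference.  Nodal: per-triangle
  v_K = grad A_t / |grad A_t|², area-weighted vector average over each
  node's patch of incident triangles, speed = magnitude of the average
  (a magnitude-averaging mode exists for sensitivity checks).  The
  estimator is exact for affine activation fields on any triangulation;
  elements with an unactivated vertex or |grad A_t| below a floor are
  excluded with weight renormalisation.
* **Electrograms.**  Unipolar extracellular potentials sampled at exactly
  1 kHz at the two interface probes 2 mm apart (probe offsets are exact
  multiples of hY, so node snapping is lossless at the default
  resolution); bipolar = Ve2 − Ve1.

## Fiber fields

For the parametric strand the fibers are the exact tangents of the bent
longitudinal lines ((0,1) when straight).  For arbitrary muscle meshes a
rule-based field is generated from a harmonic potential: solve
Δφ = 0 with φ = 0 / φ = 1 on two boundary sets and zero flux elsewhere,
f = ∇φ/|∇φ| per element.  The two constructions agree within a few
degrees on bent strands at production resolution, and the harmonic field
satisfies the discrete maximum principle 0 ≤ φ ≤ 1.  Normalisation to
unit length is required because the conductivity construction assumes a
unit fiber axis.

## Experiment presets and problem sizes

The experiment runner exposes the study's sweeps as named presets
(thickness × curvature without bath; longitudinal/transverse conductivity
scalings; 6 mm endocardial bath; dual 3 mm baths; bath-size sweep;
electrogram tables).  Curvature grids use the named anchors κ ∈ {−π/2,
0, π/2} cm⁻¹ plus ±π/4 intermediates.  The dual-bath case uses symmetric
3 mm layers spanning the same longitudinal extent as the endocardial
bath.

The acceptance script runs single-configuration quantities (baseline CV,
conductivity scalings, manifold-limit bath CV, negative-curvature bath
case, electrogram peaks) at the full production resolution and the two
curvature sweeps plus the bath-thickness sweep at a 2× coarser mesh.
Coarsening by 2× changes the planar CV by < 3% (tested) and preserves
every ordering and relative conclusion; the sweep outputs are relative
measures by construction.

## What the synthetic geometry does and does not represent

The parametric strand isolates three geometric factors — muscle
thickness, interface curvature, bath depth — under uniform properties.
It does not represent: spatially varying wall thickness or curvature in
two directions, transmurally rotating fibers, tissue heterogeneity or
fibrosis, or a patient-specific atrial wall; conclusions about those
require volumetric anatomical models.  Passing tests therefore establish
the correctness of the solver and estimators and the direction/magnitude
of the geometric effects in the idealised setting, not clinical
generality.

## Known limitations

* The membrane implementation follows the published 1998 parameter set;
  concentration-stabilised variants of that model differ by a few
  percent in upstroke and hence CV.  Absolute velocities carry that
  systematic offset (≈ +4%); ratios, orderings, curvature/bath effects
  and threshold classifications (e.g. bipolar peaks below/above 1 mV) do
  not.
* First-order time integration: the scheme is robust for the
  discontinuous-parameter atrial model but only first-order accurate;
  the cubic-reaction model provides the smooth-kinetics verification
  path.
* 2-D cross-section: transmural propagation and curvature in two
  directions are out of scope.
* The unstimulated atrial cell drifts very slowly in its ionic
  concentrations (fractions of a mM over tens of seconds), so the
  equilibration criterion |dV/dt| < 10⁻⁶ mV/ms may not be met within the
  10 s horizon; the resting potential is nonetheless stable to well
  within the reported band, and the residual drift is reported.
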