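# Methods

`osteoload` estimates the internal loads carried by a plate osteosynthesis
bridging a 3 mm mid-diaphyseal metacarpal osteotomy during non-weight-bearing
rehabilitation motion (fingertip-to-palm finger flexion and wrist flexion),
and assesses whether an adhesive fixation patch could tolerate those loads.
The measurement principle is inverse: because the construct's stiffness is
known, the rigid motion of the bone fragments — tracked optically in the
laboratory setting this package emulates — determines the forces and moments
the fixation transmits. The package replaces the cadaveric measurement chain
(imaging, surgery, optical tracking, commercial FE and statistics software)
with a parametric synthetic construct and cohort, a small finite-element
solver, and an in-repo statistics chain, so the whole analysis runs from a
single seed on one desk-scale CPU.

## Construct model

Units are mm / N / MPa throughout, so moments are natively N·mm.
Coordinates: x along the bone axis (proximal → distal, origin at the gap
center), y dorsal (the plate side), z perpendicular to the sagittal
(flexion) plane. The out-of-plane bending moment Mz about z is the primary
outcome; the sign convention makes flexion that stretches the plate's dorsal
fiber positive.

Bone fragments are idealized as straight tubes — a cortical shell
(default outer radius 4.5 mm, thickness 1.5 mm, typical metacarpal scale)
around a trabecular core — separated by an open 3 mm gap. The imaging-based
specimen-specific geometry of the laboratory workflow is out of scope; every
dimension is configurable. The plate (24.25 × 4.25 mm; thickness is not a
reported dimension — default 1.0 mm, configurable) rests tangent to the
dorsal surface and is connected to the bone only through four bicortical
screws at ±5 and ±10 mm from the gap center. The gap is assumed open
throughout (no fragment contact): a 3 mm gap does not close under
rehabilitation-scale motion.

Default materials (homogeneous per region): cortical bone 15 GPa, trabecular
bone 0.5 GPa, PEEK plate 3.6 GPa (ν = 0.38), screw (titanium-like) 110 GPa.
None of these are reported values from the emulated study; they are standard
literature-scale constants, and an optional density power law
E = a·ρ^b (defaults a = 6850 MPa, b = 1.49) supports heterogeneous bone
fields. Because the analysis is displacement-driven and the plate is by far
the most compliant member in the load path, the extracted plate moments are
insensitive to the bone constants.

## Meshing

The mesher is a deterministic structured-to-tetrahedral subdivision —
no third-party mesh generator, so meshes are bit-reproducible. Each bone
fragment is a cylindrical scaffold (radial × azimuthal × axial cells,
wedges on the axis), the plate a rectilinear scaffold. Every cell is split
through its centroid with quad faces diagonalized through their smallest
global node id; that rule triangulates shared faces identically on both
sides, making the mesh conforming everywhere including the azimuthal seam.
Linear tets are promoted to 10-node quadratic tetrahedra (tet10) with
mid-edge nodes at edge midpoints.

Numerical details:

* ring radii are inflated by √(h/sin h) so polygonal cross-section areas
  equal the analytic annulus areas — per-region volume conservation is then
  near-exact at any resolution (the inflation means plate and bone surfaces
  may overlap by a few percent of radius; immaterial, as the bodies interact
  only through ties);
* screw holes in the plate are volume-matched staircase holes: the
  through-thickness cell columns nearest each screw axis are removed, count
  chosen so removed volume ≈ πr²t (at very coarse resolutions where a hole
  is smaller than half a cell, no cells are removed);
* edge-length targets follow a two-zone scheme — refined (default
  0.25 mm × scale_factor) for the plate and the axial grading of bone near
  the plate, coarse (1 mm × scale_factor) elsewhere; scaffold cell sides are
  the target divided by √2 so face diagonals also respect the bound.
  A structured cylindrical grid cannot refine one azimuthal sector
  conformally, so bone azimuthal/radial resolution follows the coarse
  target; far-field axial cell length is capped at 3× the transverse cell
  size to bound element anisotropy;
* quality gate: minimum scaled Jacobian (√2·6V over the product of the
  three corner edges, minimized over corners) ≥ 0.05, else the mesh is
  rejected.

Screws are not meshed. Each screw is a rigid kinematic tie group coupling
the bone nodes inside the screw cylinder (grown from the screw radius until
the set is bicortical, capped below half the screw spacing) with the plate
nodes on the hole rim. Rigid ties have no penalty or Lagrange parameters to
tune, at the cost of locally rigidifying a node neighborhood that shrinks
with mesh refinement and of artificial stress spikes at the tie boundary
(see Safety below).

`scale_factor` is the single desk-scale dial: 1.0 reproduces the reference
edge-length parameters (0.25 mm refined / 1 mm coarse — a cluster-scale
mesh), the package default 4.0 gives ≈20k elements / 90k DOF and a direct
solve in about a minute. The mesh-convergence harness
(`check_convergence`) guards the choice: on the default construct the
gap-center moment changes by 3.6% between scale factors 8 and 4, inside the
5% convergence criterion the analysis inherits.

## FE solver

Small-strain isotropic linear elasticity on tet10 elements, 4-point Gauss
quadrature (exact for the straight-edged quadratic element), assembled
sparse and solved by direct factorization (SuperLU, COLAMD ordering).
Boundary conditions: the proximal end face is pinned (all translations
fixed — a face clamp, the pin-support idealization), the distal end face is
driven with prescribed displacements; individual components can be masked
(used by the beam oracles). Tie groups are eliminated master–slave to one
6-DOF rigid body each (linearized rotation). The solver verifies a relative
free-DOF residual below 1e-8 (one iterative-refinement step if needed),
rejects under-constrained systems, and returns nodal reactions K·u. The
patch test (uniform-strain reproduction) holds to machine precision;
a 24.25 × 4.25 × 1 mm cantilever's tip reaction matches Euler–Bernoulli
3EIδ/L³ within 3% at the suite's mesh.

## Section loads

The six load components across a transverse cut of the plate are recovered
by free-body summation: internal nodal forces Σ K_e·u_e of one side's
elements, accumulated at the interface nodes, give exactly the force the
removed side exerts on the kept side at the discrete level — no integration
error beyond the FE solution itself. Moments are taken about the plate
cross-section centroid so Mz compares directly with beam theory. Elements
are attributed to sides by centroid, which works for any plane position
inside the gap span (the only region where the plate is the sole material
crossing). Proximal/distal free bodies are antisymmetric to 1e-12 and the
moment transport law Mz(Δx) = Mz(0) − Fy·Δx holds to the same precision.
A traction-integration route (midpoint quadrature of σ·n̂ over the
cross-section) is provided as an independent cross-check; it carries
pointwise-stress interpolation error and is held to a 10% tolerance.

## Displacement trajectories and calibration

The laboratory workflow does not decompose marker motion into translation
and rotation, so the generator must pick a kinematic form. Pure transverse
translation of the distal fragment produces antisymmetric double-curvature
bending of the plate with its inflection point at the gap center — the
gap-center moment would be a near-zero cancellation, useless as a primary
outcome. The package therefore drives flexion as what the stiff dorsal
plate kinematically enforces: rotation of the distal fragment about the
z-axis through the plate mid-surface at the gap center (default
−0.5°/mm of machine travel; the sign makes flexion open the gap dorsally),
plus a small volar translation coupling (−0.05 mm/mm) so the shear force
and the transport law are exercised. At the default desk scale this yields
Mz = +1.13 N·mm per mm of travel.

A trajectory template is a monotone displacement-amplitude profile over
normalized travel, stored at six knots and interpolated monotonically
(PCHIP). Because the model is linear, calibrating a template to a target
moment curve is one FE solve (the unit moment) plus a per-step division;
the per-step scalar root-find the interface promises degenerates to exactly
that. Targets are benchmark cadaveric moment levels per digit and test
(step-wise means on the six-step reporting grid, e.g. peaks 8.57 / 4.71 /
4.88 N·mm for digits 2–4 in fingertip-to-palm motion). Two subtleties:

* wrist-flexion targets are printed on the grid of the *analyzed* window
  (the first half of travel — the second half overextends natural flexion),
  so those template knots sit at raw travel s/2 and the profile continues
  beyond s = 0.5 at half its final slope; that tail is generated but never
  analyzed;
* the digit-3 wrist-flexion target dips at its last step (3.03 →
  2.98 N·mm); a monotone displacement path cannot reproduce a falling
  moment in a linear model, so calibration applies a running-maximum repair
  (that step lands 1.68% above target, inside the 2% round-trip tolerance).

## Cohort and noise model

The default design mirrors a five-donor roster (covariates: mean age 42.6 y,
population-SD 5.54; mean BMI 27.98): digits 2–4, five trials each with
trials 3–5 retained (earlier trials absorb setup artifacts), and the fourth
digit of hand 2 excluded (severed flexor tendon) — per-digit group sizes
15/15/12 and 42 records per test.

Noise enters the displacement amplitude as a multiplicative log-normal
specimen effect × an additive Gaussian trial perturbation, both expressed
in moment units at the template's peak so they are comparable with reported
step SDs. One standard-normal draw per hand (shared across its digits and
tests — a globally stiff or lax specimen) is scaled by each template's
relative specimen SD. Defaults split the peak-step SD 0.8/0.6 between
specimen and trial levels (0.8² + 0.6² = 1, so the generated group SD
matches the benchmark SD scale). The trial factor is floored at 0.05 to
keep paths monotone-forward; with noise and specimen effects at zero the
generator reproduces the template bit-exactly. All randomness descends
deterministically from one integer seed.

What the generator does *not* emulate: specimen-specific geometry and
density fields, trial-to-trial variation of the curve *shape* (noise scales
amplitude only), marker measurement noise along the path, soft-tissue and
tendon-path effects, and any nonlinearity of the real construct. Passing
tests therefore validate the pipeline's mechanics, bookkeeping and
statistics — not the biological variability of real specimens.

## Trajectory processing

Travel is normalized to s ∈ [0,1] per trial (affine-invariant).
Fingertip-to-palm trials are analyzed over the full range; wrist-flexion
trials over s ≤ 0.5 only, re-normalized onto the 0–1 reporting grid
(default; a flag preserves the raw half-window indexing instead, since the
printed convention is ambiguous). Curves are resampled onto the grid
{0, 0.2, …, 1} by linear interpolation — deterministic and
monotonicity-preserving; extrapolation is an error. The per-trial maximum
is taken on the raw analyzed window, not the resampled grid. Grouped
summaries report mean ± SD per (test, digit) at each step; step 0 is
exactly 0 ± 0.

## Statistics

Implemented from their defining formulas, with scipy supplying only the
reference distributions (t, F, normal, studentized range): descriptives
under both SD conventions, paired t, Shapiro–Wilk (Royston's AS R94
polynomial approximation, exact p for n = 3), Levene (mean-centered
classic form; median variant available), classic one-way ANOVA, Welch
ANOVA with Welch–Satterthwaite df, and Games–Howell with per-pair Welch df
on the studentized-range distribution. scipy and pingouin serve as
independent cross-check oracles in the tests (agreement to 3 decimal
places on random datasets; Welch also validated against R's `oneway.test`).

The decision gate: Shapiro–Wilk per group is reported but never diverts the
chain (one-way ANOVA is robust to moderate non-normality); Levene selects
Welch + Games–Howell under heteroscedasticity, otherwise classic ANOVA.
No named post hoc is prescribed on the homoscedastic branch, so the gate
emits unadjusted pairwise Welch t-tests with an explicit warning rather
than guessing a procedure. Outliers are retained everywhere. The paired
test-1 vs test-2 comparison pairs per retained trial (42 pairs);
α = 0.05 throughout. Simulation checks: Welch's type-I error under
heteroscedastic H₀ (sds 1/1/3, ns 15/15/12) is 0.0505 ± 0.0013, inside the
nominal band, while the classic F-test inflates to ≈0.10 — the reason the
gate exists.

Degenerate inputs are reported, not hidden: zero-variance groups skip
normality with a note, all-n=2 Levene returns an infinite statistic with
its df bookkeeping, constant paired differences flag p → 0 or 1.

## Safety assessment

Demand is the pooled maximum moment (group-size-weighted over digits:
6.14 N·mm for fingertip-to-palm at the benchmark levels). Capacity comes
from published monotonic bending-to-failure of the cured adhesive patch:
lowest 728 N·mm, mean 1220 ± 300 N·mm — measured on an ovine phalanx
four-point-bending model, a different bone and geometry, so every report
carries the cross-model caveat verbatim rather than any adjustment.
The safety factor is capacity/demand (≈119 on the lowest basis; pass
threshold configurable, default 1). The flexural-stress check solves the
construct with the plate envelope carrying the composite's flexural modulus
(6.6 GPa) and compares the maximum principal stress against the 69 MPa
flexural strength. On full constructs that comparison is made over the
gap-bridging span — the patch's critical flexural section — because the
rigid-tie idealization produces artificial stress spikes at the screw hole
rims that a flexural-strength criterion does not govern; at the pooled
demand the bridging-span stress is ≈18 MPa (utilization 26%).

## Problem sizes and tolerances

Defaults chosen for a single-CPU desk run: scale_factor 4 (≈20k tet10,
90k DOF, ~1 min direct solve) for production numbers; the test suite uses
scale factors 8–16 (seconds per solve) except where an oracle's tolerance
requires better resolution. The convergence study runs scale factors
16 → 8 → 4. One FE solve serves an entire cohort through linearity.
Key tolerances: patch test 1e-10; free-body antisymmetry and moment
transport 1e-6 (observed 1e-12); beam oracles 5%; stress-integration
cross-check 10%; calibration round-trip 2%; solver residual 1e-8 relative.

## Known limitations

Linear elasticity only — no contact, no geometric or material nonlinearity,
no failure or fatigue modelling (capacity is compared, not simulated).
Rigid screw ties overstate local stiffness near screws and invalidate
peri-screw stress fields. The tubular geometry ignores anatomical curvature
and the metacarpal's flaring ends; absolute moment magnitudes are
calibrated to benchmark levels rather than predicted ab initio. The
wrist-flexion profile beyond half-travel is a synthetic continuation with
no physical claim. Welch/Games–Howell inherit the usual small-sample
caveats at these group sizes; trials within a digit are treated as
independent replicates by the chain, as in the emulated analysis, although
the generator (and reality) correlate them through the specimen effect.
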