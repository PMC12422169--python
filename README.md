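# osteoload

Internal loads in plate-fixed metacarpal osteotomies during hand
rehabilitation, computed by displacement-driven finite-element analysis —
with a synthetic construct and cohort generator in place of the cadaveric
experiment, the statistics chain for grouped bending-moment maxima, and a
safety assessment of an adhesive osteosynthesis patch.

## The problem

After a metacarpal shaft fracture is plated, early motion speeds recovery —
but only if the fixation tolerates the internal loads of rehabilitation
exercises, and those loads cannot be measured directly. The inverse
approach: fix a 3 mm mid-diaphyseal osteotomy (a worst-case comminuted
fracture with no load sharing across the gap) with a plate of known
stiffness, track how the bone fragments move during fingertip-to-palm and
wrist-flexion motion, and replay that motion through a finite-element model
of the construct. The force and moment transmitted across a virtual cut of
the plate — especially the bending moment Mz about the axis perpendicular
to the flexion plane — is the load any fixation device at that location
must survive. Comparing that demand with the published failure moments of
a light-curable composite patch (AdhFix) answers whether adhesive
osteosynthesis could tolerate early rehabilitation.

This package is for biomechanics researchers and engineers who want that
pipeline end-to-end as inspectable, testable Python: parametric construct
geometry, conforming quadratic-tetrahedral meshing with screws as rigid
kinematic ties, a small-strain linear-elastic tet10 solver, free-body
section-load extraction, normalized-trajectory aggregation, the
Welch-ANOVA/Games–Howell statistics chain, and capacity-vs-demand safety
reporting.

## The model in brief

A construct = two tubular bone fragments (cortical shell + trabecular
core) separated by an open 3 mm gap, bridged by a 24.25 × 4.25 mm plate on
the dorsal surface, fixed by four bicortical screws at ±5 and ±10 mm.
Flexion is driven as prescribed displacement of the distal end face —
rotation about the flexion axis through the plate mid-surface — with the
proximal face pinned. For a linear model one solve gives the unit moment
`m = Mz per mm of travel`; a trial's moment curve is `M(s) = a(s)·m` with
`a(s)` the (monotone) displacement-amplitude profile, so calibrating
profiles to target moment curves is a per-step division. Section loads are
exact discrete free-body sums: `F = Σ_{interface} Σ_{e∈side} K_e u_e`,
with moments about the section centroid, satisfying the transport law
`Mz(Δx) = Mz(0) − Fy·Δx` to machine precision. Grouped per-trial maxima
feed Shapiro–Wilk (report), Levene (gate), then Welch ANOVA with
Games–Howell or classic one-way ANOVA; the safety factor is
`capacity / demand`.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from osteoload import MeshParams, run_study

res = run_study(seed=1, mesh_params=MeshParams(scale_factor=8.0))
print(f"unit moment: {res.unit_moment:.3f} N*mm per mm travel")
m1, s1 = res.pooled_max[1]; m2, s2 = res.pooled_max[2]
print(f"fingertip-to-palm pooled max: {m1:.2f} +/- {s1:.2f} N*mm")
print(f"wrist flexion pooled max:     {m2:.2f} +/- {s2:.2f} N*mm")
print(res.paired)
print(res.safety)
```

prints (exact values for this seed):

```
unit moment: 1.126 N*mm per mm travel
fingertip-to-palm pooled max: 5.82 +/- 2.28 N*mm
wrist flexion pooled max:     3.17 +/- 1.62 N*mm
paired t: stat=12.22, df=41, p=3.022e-15 (significant at alpha=0.05)
demand 5.82 N*mm vs lowest capacity 728 N*mm: safety factor 125.0 (PASS at >= 1.0)
```

Reading the numbers: one FE solve of the synthetic construct converts
1 mm of flexion travel into 1.126 N·mm of plate bending moment at the gap
center. The five-hand synthetic cohort (digits 2–4, trials 3–5, group
sizes 15/15/12) is calibrated so per-digit moment curves land at benchmark
cadaveric levels, with specimen and trial noise at benchmark-like SDs —
hence pooled maxima near 6 N·mm (fingertip-to-palm) and ~3.4 N·mm (wrist
flexion), clearly separated by the paired test. Demand sits two orders of
magnitude below the patch's lowest published failure moment (728 N·mm).

The `examples/` scripts walk each capability separately: the forward
model (`01`), mesh convergence (`02`), cohort generation and summary
tables (`03`), the statistics chain (`04`) and the safety assessment
(`05`). Each prints what it computes and what the numbers mean.

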