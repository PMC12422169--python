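"""End-to-end study pipeline.

Because the model is linear-elastic and every trial of a construct shares
one displacement pattern, the whole cohort needs a single FE solve: the
unit-amplitude section loads are computed once and every trial's moment
curve is that unit moment scaled by the trial's displacement-amplitude
profile.  Calibration of trajectory templates to target moment curves is
then a per-step division (see :func:`osteoload.synthetic.calibrate_template`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import ConstructGeometry, default_construct
from .meshing import (
    DEFAULT_MATERIALS,
    MaterialField,
    Mesh,
    MeshParams,
    assign_materials,
    assign_ties,
    mesh_construct,
)
from .sections import CutPlane, SectionLoads, scaled_moment_curve, section_loads
from .solver import BoundaryConditions, SolutionField, assemble, solve
from .synthetic import (
    CohortDesign,
    DisplacementPattern,
    TrialInput,
    default_cohort_design,
    default_templates,
    generate_cohort,
)
from .trajectory import CohortSummary, TrialRecord, summarize_cohort
from .stats import (
    GateResult,
    TestReport,
    analysis_gate,
    paired_t,
    weighted_group_mean,
)
from .safety import ADHFIX_CAPACITY, SafetyReport, safety_factor

__all__ = [
    "ConstructModel",
    "build_model",
    "solve_pattern",
    "unit_section_loads",
    "unit_cut_moment",
    "bending_moment_pipeline",
    "StudyResult",
    "run_study",
]


@dataclass
class ConstructModel:
    """Meshed, material-assigned construct ready for displacement-driven
    solves."""

    geometry: ConstructGeometry
    params: MeshParams
    mesh: Mesh
    materials: MaterialField
    ties: list[np.ndarray]
    pattern: DisplacementPattern


def build_model(
    geometry: ConstructGeometry | None = None,
    mesh_params: MeshParams | None = None,
    materials_spec: Mapping[str, tuple[float, float]] | None = None,
    pattern: DisplacementPattern | None = None,
) -> ConstructModel:
    geometry = geometry or default_construct()
    mesh_params = mesh_params or MeshParams()
    mesh = mesh_construct(geometry, mesh_params)
    materials = assign_materials(mesh, materials_spec or DEFAULT_MATERIALS)
    ties = assign_ties(mesh, geometry)
    pattern = pattern or DisplacementPattern.for_geometry(geometry)
    return ConstructModel(
        geometry=geometry, params=mesh_params, mesh=mesh,
        materials=materials, ties=ties, pattern=pattern,
    )


def solve_pattern(model: ConstructModel, amplitude: float = 1.0) -> SolutionField:
    """Solve the construct under the distal-fragment displacement pattern
    at the given travel amplitude (mm): pin support on the proximal end
    face, pattern displacement on the distal end face."""
    mesh = model.mesh
    distal = mesh.node_sets["applied_displacement"]
    vals = model.pattern.displacements(mesh.nodes[distal], amplitude)
    bcs = BoundaryConditions(
        pinned=mesh.node_sets["pin_support"],
        prescribed=distal,
        prescribed_values=vals,
        tie_groups=model.ties,
    )
    K = assemble(mesh, model.materials)
    return solve(K, bcs, mesh.nodes)


def unit_section_loads(
    model: ConstructModel, plane: CutPlane | None = None
) -> tuple[SectionLoads, SolutionField]:
    """Section loads at the cut plane for unit travel amplitude."""
    plane = plane or CutPlane.at_gap_center(model.geometry)
    sol = solve_pattern(model, amplitude=1.0)
    loads = section_loads(
        sol, model.mesh, model.materials, plane, side="distal", geometry=model.geometry
    )
    return loads, sol


def unit_cut_moment(
    geometry: ConstructGeometry | None = None,
    materials_spec: Mapping[str, tuple[float, float]] | None = None,
    mesh_params: MeshParams | None = None,
    pattern: DisplacementPattern | None = None,
) -> float:
    """|Mz| at the gap center per mm of travel amplitude (calibration
    constant of the forward model)."""
    model = build_model(geometry, mesh_params, materials_spec, pattern)
    loads, _ = unit_section_loads(model)
    return abs(loads.Mz)


def bending_moment_pipeline(
    geometry: ConstructGeometry, params: MeshParams, amplitude: float = 1.0
) -> float:
    """Mesh -> solve -> |Mz| at gap center under the standard flexion
    pattern at fixed amplitude; the quantity tracked by the mesh
    convergence study."""
    model = build_model(geometry, params)
    loads, _ = unit_section_loads(model)
    return abs(loads.Mz) * amplitude


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


@dataclass
class StudyResult:
    """Everything the study computes, ready for reporting."""

    unit_moment: float  # N*mm per mm travel amplitude
    records: list[TrialRecord]
    summary: CohortSummary
    gates: dict[int, GateResult]  # per test
    paired: TestReport
    pooled_max: dict[int, tuple[float, float]]  # test -> (weighted mean, sd)
    safety: SafetyReport
    design: CohortDesign

    def report(self) -> str:
        lines = [f"unit cut-plane moment: {self.unit_moment:.4g} N*mm per mm travel"]
        for test in sorted(self.gates):
            mean, sd = self.pooled_max[test]
            lines.append(
                f"test {test}: pooled max moment {mean:.2f} +/- {sd:.2f} N*mm"
            )
            lines.append(self.gates[test].log())
        lines.append(str(self.paired))
        lines.append(str(self.safety))
        return "\n".join(lines)


def moments_for_trial(trial: TrialInput, unit_moment: float) -> TrialRecord:
    """Fill a trial's moment curve by linear scaling of the unit moment."""
    moment = np.abs(trial.path.amplitude * unit_moment)
    return TrialRecord(
        hand=trial.hand, digit=trial.digit, test=trial.test, trial=trial.trial,
        travel=trial.path.travel.copy(), moment=moment,
    ).process()


def run_study(
    seed: int = 0,
    design: CohortDesign | None = None,
    geometry: ConstructGeometry | None = None,
    mesh_params: MeshParams | None = None,
    noise_scale: float = 1.0,
    unit_moment: float | None = None,
    capacity=ADHFIX_CAPACITY,
    alpha: float = 0.05,
    paired_by: str = "trial",
) -> StudyResult:
    """Run the complete synthetic study.

    Generates the cohort, fills moment curves through the forward model
    (one FE solve, or a precomputed ``unit_moment``), summarizes on the
    reporting grid, runs the statistics chain per test, the paired test-1
    vs test-2 comparison, and the safety assessment of the pooled demand.
    """
    design = design or default_cohort_design()
    if unit_moment is None:
        unit_moment = unit_cut_moment(geometry, None, mesh_params)
    templates = default_templates(unit_moment, noise_scale=noise_scale)
    cohort = generate_cohort(design, templates, seed=seed)
    records = [moments_for_trial(t, unit_moment) for t in cohort]
    summary = summarize_cohort(records)

    gates: dict[int, GateResult] = {}
    pooled: dict[int, tuple[float, float]] = {}
    maxima = summary.maxima
    for test in sorted(int(t) for t in maxima["test"].unique()):
        digits = sorted(int(d) for d in maxima["digit"].unique())
        groups = [summary.group_maxima(test, d) for d in digits]
        labels = [f"digit {d}" for d in digits]
        from .stats import GroupData

        gates[test] = analysis_gate(
            [GroupData(l, g) for l, g in zip(labels, groups)], alpha=alpha
        )
        all_max = maxima.loc[maxima["test"] == test, "max_moment"]
        pooled[test] = (
            weighted_group_mean(
                [g.mean() for g in groups], [len(g) for g in groups]
            ),
            float(all_max.std(ddof=1)),
        )

    # paired comparison: test-1 vs test-2 maxima matched per retained trial
    # (default) or per digit mean
    if paired_by not in ("trial", "digit_mean"):
        raise ValueError("paired_by must be 'trial' or 'digit_mean'")
    index = ["hand", "digit", "trial"] if paired_by == "trial" else ["hand", "digit"]
    wide = maxima.pivot_table(index=index, columns="test", values="max_moment")
    tests = sorted(maxima["test"].unique())
    if len(tests) >= 2:
        paired = paired_t(wide[tests[0]].to_numpy(), wide[tests[1]].to_numpy(), alpha)
    else:
        raise ValueError("paired comparison needs both tests in the cohort")

    demand = pooled[1][0] if 1 in pooled else max(m for m, _ in pooled.values())
    safety = safety_factor(demand, capacity, basis="lowest")
    return StudyResult(
        unit_moment=unit_moment, records=records, summary=summary, gates=gates,
        paired=paired, pooled_max=pooled, safety=safety, design=design,
    )
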