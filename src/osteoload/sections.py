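"""Section loads at a cut plane through the plate.

The six internal load components transmitted across a virtual transverse
cut of the plate are recovered by free-body summation of internal nodal
forces: for the chosen side's elements, f = sum(K_e u_e) is accumulated at
the interface nodes, giving exactly the force the removed side exerts on
the kept side at the discrete level (no integration error on top of the
FE solution).  Moments are taken about the plate cross-section centroid so
the out-of-plane component Mz is directly comparable with beam theory.

A stress-integration variant (trapezoid quadrature of the traction over
the cross-section) is provided as an independent cross-check; it carries
interpolation error and is held to a looser tolerance.

Sign convention: loads are reported from the distal-side free body, i.e.
the action of the proximal side on the distal fragment; sagittal-plane
flexion that stretches the plate's outer (dorsal) fiber gives positive Mz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import ConstructGeometry
from .meshing import MaterialField, Mesh
from .solver import SolutionField, internal_forces

__all__ = [
    "CutPlane",
    "SectionLoads",
    "section_loads",
    "moment_curve",
    "scaled_moment_curve",
    "section_loads_stress_integration",
]


@dataclass(frozen=True)
class CutPlane:
    """Transverse cut through the plate at axial position x (mm).

    The plane's normal is the bone long axis; the moment reference point
    is the plate cross-section centroid at that position.  The plane must
    lie within the gap span, where the plate is the only material crossing.
    """

    position: float
    reference_point: tuple[float, float, float]

    @classmethod
    def at_gap_center(cls, geometry: ConstructGeometry, position: float = 0.0) -> "CutPlane":
        if abs(position) >= geometry.half_gap:
            raise ValueError(
                f"cut plane at x={position} lies outside the gap span "
                f"(+/-{geometry.half_gap} mm); it would intersect bone"
            )
        ref = (
            position,
            geometry.plate_bottom + geometry.plate_thickness / 2.0,
            0.0,
        )
        return cls(position=position, reference_point=ref)


@dataclass
class SectionLoads:
    """Three forces (N) and three moments (N*mm) about the reference point."""

    Fx: float
    Fy: float
    Fz: float
    Mx: float
    My: float
    Mz: float
    step: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.Fx, self.Fy, self.Fz, self.Mx, self.My, self.Mz])

    def scaled(self, factor: float, step: float | None = None) -> "SectionLoads":
        v = self.as_array() * factor
        return SectionLoads(*v, step=self.step if step is None else step)


def _split_elements(mesh: Mesh, position: float) -> tuple[np.ndarray, np.ndarray]:
    cx = mesh.element_centroids()[:, 0]
    return np.nonzero(cx > position)[0], np.nonzero(cx <= position)[0]


def section_loads(
    solution: SolutionField,
    mesh: Mesh,
    materials: MaterialField,
    plane: CutPlane,
    side: str = "distal",
    geometry: ConstructGeometry | None = None,
) -> SectionLoads:
    """Free-body section loads at ``plane`` from the chosen side.

    Elements are attributed to a side by centroid; interface nodes (shared
    by both sides) accumulate the side's internal nodal forces, whose
    resultant is the force transmitted across the cut.  ``side='proximal'``
    returns the componentwise negative of ``side='distal'``.
    """
    if side not in ("distal", "proximal"):
        raise ValueError("side must be 'distal' or 'proximal'")
    if geometry is not None and abs(plane.position) >= geometry.half_gap:
        raise ValueError("cut plane outside the gap span")
    distal_els, proximal_els = _split_elements(mesh, plane.position)
    own_els = distal_els if side == "distal" else proximal_els
    other_els = proximal_els if side == "distal" else distal_els
    in_own = np.zeros(mesh.n_nodes, bool)
    in_other = np.zeros(mesh.n_nodes, bool)
    in_own[mesh.elements[own_els].ravel()] = True
    in_other[mesh.elements[other_els].ravel()] = True
    iface = np.nonzero(in_own & in_other)[0]
    if len(iface) == 0:
        raise ValueError(f"cut plane at x={plane.position} intersects no elements")
    f = internal_forces(mesh, materials, solution.displacements, own_els)
    F = f[iface].sum(axis=0)
    r = mesh.nodes[iface] - np.asarray(plane.reference_point)
    M = np.cross(r, f[iface]).sum(axis=0)
    # distal free body: action of proximal on distal = +sum of distal-side
    # internal forces at the interface (see solver internal-force convention)
    return SectionLoads(F[0], F[1], F[2], M[0], M[1], M[2])


def moment_curve(
    solutions: Sequence[SolutionField],
    mesh: Mesh,
    materials: MaterialField,
    plane: CutPlane,
    steps: Sequence[float] | None = None,
    side: str = "distal",
) -> list[SectionLoads]:
    """Section loads per loading step (one solved state each)."""
    solutions = list(solutions)
    if len(solutions) < 2:
        raise ValueError("need at least 2 loading steps")
    steps = list(steps) if steps is not None else list(range(len(solutions)))
    out = []
    for sol, s in zip(solutions, steps):
        loads = section_loads(sol, mesh, materials, plane, side=side)
        loads.step = float(s)
        out.append(loads)
    return out


def scaled_moment_curve(
    unit_loads: SectionLoads, amplitudes: Sequence[float], steps: Sequence[float] | None = None
) -> list[SectionLoads]:
    """Per-step loads for a linear model: amplitude x unit-amplitude loads."""
    amplitudes = np.asarray(amplitudes, float)
    steps = np.asarray(steps, float) if steps is not None else amplitudes
    return [unit_loads.scaled(a, step=s) for a, s in zip(amplitudes, steps)]


def section_loads_stress_integration(
    solution: SolutionField,
    mesh: Mesh,
    materials: MaterialField,
    plane: CutPlane,
    geometry: ConstructGeometry,
    n_grid: tuple[int, int] = (8, 24),
) -> SectionLoads:
    """Cross-check: integrate the traction sigma . x_hat over the plate
    cross-section at the cut plane (distal-side convention).

    Samples element stresses on a cell-centered rectangular grid over the
    plate section and applies midpoint quadrature.  Interpolation-limited;
    agreement with :func:`section_loads` within ~10% is expected.
    """
    from .solver import _stresses_at, _shape_gradients  # reuse kernels

    x0 = plane.position
    ys = np.linspace(geometry.plate_bottom, geometry.plate_bottom + geometry.plate_thickness, n_grid[0] + 1)
    zs = np.linspace(-geometry.plate_width / 2.0, geometry.plate_width / 2.0, n_grid[1] + 1)
    yc = 0.5 * (ys[:-1] + ys[1:])
    zc = 0.5 * (zs[:-1] + zs[1:])
    dA = (ys[1] - ys[0]) * (zs[1] - zs[0])
    pts = np.array([[x0, y, z] for y in yc for z in zc])

    # candidate elements: plate elements whose bounding box straddles the plane
    plate_ids = np.nonzero(mesh.region_mask("plate"))[0]
    corners = mesh.nodes[mesh.elements[plate_ids][:, :4]]
    xmin, xmax = corners[..., 0].min(axis=1), corners[..., 0].max(axis=1)
    cand = plate_ids[(xmin <= x0 + 1e-9) & (xmax >= x0 - 1e-9)]
    if len(cand) == 0:
        raise ValueError("cut plane intersects no plate elements")

    # locate each sample point (barycentric test against candidates)
    c = mesh.nodes[mesh.elements[cand][:, :4]]
    T = np.stack([c[:, 0] - c[:, 3], c[:, 1] - c[:, 3], c[:, 2] - c[:, 3]], axis=2)
    Tinv = np.linalg.inv(T)
    F = np.zeros(3)
    M = np.zeros(3)
    ref = np.asarray(plane.reference_point)
    for p in pts:
        lam = np.einsum("eij,ej->ei", Tinv, p - c[:, 3])
        l4 = 1.0 - lam.sum(axis=1)
        ok = np.nonzero(
            (lam >= -1e-9).all(axis=1) & (l4 >= -1e-9)
        )[0]
        if len(ok) == 0:
            continue  # staircase boundary miss
        e = ok[0]
        xi = lam[e]
        grads = _shape_gradients(xi[None, :])
        eid = cand[e]
        sig6 = _stresses_at(
            _SingleElementView(mesh, eid), _single_material(materials, eid),
            solution.displacements, grads,
        )[0, 0]
        S = np.array(
            [
                [sig6[0], sig6[3], sig6[5]],
                [sig6[3], sig6[1], sig6[4]],
                [sig6[5], sig6[4], sig6[2]],
            ]
        )
        # distal free body: its cut face has outward normal -x, so the
        # traction exerted on it is sigma . (-x_hat)
        t = -(S @ np.array([1.0, 0.0, 0.0]))
        F += t * dA
        M += np.cross(p - ref, t) * dA
    return SectionLoads(F[0], F[1], F[2], M[0], M[1], M[2])


class _SingleElementView:
    """Minimal mesh view exposing one element to the stress kernel."""

    def __init__(self, mesh: Mesh, eid: int):
        self.nodes = mesh.nodes
        self.elements = mesh.elements[eid : eid + 1]
        self.n_elements = 1


def _single_material(materials: MaterialField, eid: int) -> MaterialField:
    return MaterialField(
        young=materials.young[eid : eid + 1],
        poisson=materials.poisson[eid : eid + 1],
    )
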