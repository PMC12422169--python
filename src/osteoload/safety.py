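"""Fixation safety assessment: demand vs published capacity.

Compares computed internal-moment demands against the published failure
moments of an adhesive osteosynthesis patch (light-curable hydroxyapatite/
thiol-ene composite anchored by screws), and checks extreme-fiber flexural
stress against its published strength.  The capacity values come from
monotonic four-point bending to failure of the patch on an ovine phalanx
model — a different bone and geometry than the metacarpal construct, so
reports carry a cross-model caveat rather than any adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .meshing import DEFAULT_MATERIALS, MaterialField, Mesh
from .solver import SolutionField, max_principal_stress

__all__ = [
    "CapacitySpec",
    "SafetyReport",
    "PatchStressReport",
    "ADHFIX_CAPACITY",
    "adhfix_materials",
    "safety_factor",
    "patch_stress_check",
]

CROSS_MODEL_CAVEAT = (
    "capacity values measured on an ovine phalanx four-point-bending model; "
    "applied unadjusted to the metacarpal construct"
)


@dataclass(frozen=True)
class CapacitySpec:
    """Published failure/strength properties of a fixation device."""

    lowest_failure_moment: float  # N*mm
    mean_failure_moment: float  # N*mm
    failure_moment_sd: float  # N*mm
    flexural_strength: float  # MPa
    flexural_modulus: float  # MPa

    def __post_init__(self) -> None:
        vals = (
            self.lowest_failure_moment,
            self.mean_failure_moment,
            self.failure_moment_sd,
            self.flexural_strength,
            self.flexural_modulus,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all capacity values must be positive")
        if self.lowest_failure_moment > self.mean_failure_moment:
            raise ValueError("lowest failure moment cannot exceed the mean")


#: cured-composite patch: lowest / mean +/- SD failure moment (N*mm) and
#: flexural strength 69 +/- 3 MPa, flexural modulus 6.6 +/- 0.2 GPa
ADHFIX_CAPACITY = CapacitySpec(
    lowest_failure_moment=728.0,
    mean_failure_moment=1220.0,
    failure_moment_sd=300.0,
    flexural_strength=69.0,
    flexural_modulus=6600.0,
)


def adhfix_materials() -> dict[str, tuple[float, float]]:
    """Homogeneous material spec with the plate envelope given the cured
    composite's flexural modulus (patch approximated by the plate
    geometry; Poisson ratio as for the PEEK plate)."""
    spec = dict(DEFAULT_MATERIALS)
    spec["plate"] = (ADHFIX_CAPACITY.flexural_modulus, 0.38)
    return spec


@dataclass
class SafetyReport:
    """Moment-capacity safety factor for one demand level."""

    demand: float  # N*mm
    capacity: float  # N*mm
    basis: str
    safety_factor: float  # capacity / demand; inf at zero demand
    passed: bool
    min_factor: float
    caveat: str = CROSS_MODEL_CAVEAT

    def __str__(self) -> str:
        sf = "unbounded" if math.isinf(self.safety_factor) else f"{self.safety_factor:.1f}"
        return (
            f"demand {self.demand:.3g} N*mm vs {self.basis} capacity "
            f"{self.capacity:.0f} N*mm: safety factor {sf} "
            f"({'PASS' if self.passed else 'FAIL'} at >= {self.min_factor})"
        )


def safety_factor(
    demand_moment: float,
    capacity: CapacitySpec = ADHFIX_CAPACITY,
    basis: Literal["lowest", "mean"] = "lowest",
    min_factor: float = 1.0,
) -> SafetyReport:
    """Capacity / demand with the chosen capacity basis.

    Zero demand passes with an unbounded factor; negative demand is an
    error (use moment magnitudes).
    """
    if demand_moment < 0:
        raise ValueError("demand moment must be nonnegative (use magnitudes)")
    cap = (
        capacity.lowest_failure_moment if basis == "lowest" else capacity.mean_failure_moment
    )
    factor = math.inf if demand_moment == 0 else cap / demand_moment
    return SafetyReport(
        demand=float(demand_moment),
        capacity=float(cap),
        basis=basis,
        safety_factor=float(factor),
        passed=factor >= min_factor,
        min_factor=min_factor,
    )


@dataclass
class PatchStressReport:
    """Extreme-fiber stress check of the patch under a solved load state."""

    max_stress: float  # MPa, max principal over patch elements
    strength: float  # MPa
    passed: bool
    utilization: float  # max_stress / strength
    failure_scale: float  # displacement scaling that would reach strength

    def __str__(self) -> str:
        return (
            f"max principal stress {self.max_stress:.3g} MPa vs strength "
            f"{self.strength:.0f} MPa: {'PASS' if self.passed else 'FAIL'} "
            f"(utilization {self.utilization:.2%}; failure at {self.failure_scale:.3g}x load)"
        )


def bridging_span_mask(mesh: Mesh, geometry, margin: float = 0.0) -> np.ndarray:
    """Plate elements in the gap-bridging span — the patch's critical
    flexural section, away from the screw tie groups whose rigid-coupling
    idealization produces artificial local stress spikes."""
    cx = mesh.element_centroids()[:, 0]
    return mesh.region_mask("plate") & (np.abs(cx) <= geometry.half_gap + margin)


def patch_stress_check(
    solution: SolutionField,
    mesh: Mesh,
    materials: MaterialField,
    strength: float = ADHFIX_CAPACITY.flexural_strength,
    load_scale: float = 1.0,
    element_mask: np.ndarray | None = None,
) -> PatchStressReport:
    """Compare the patch's max principal stress against flexural strength.

    ``solution`` should be solved with the plate region carrying the
    patch modulus (:func:`adhfix_materials`).  ``load_scale`` linearly
    rescales the solved state to the demand level of interest.
    ``element_mask`` restricts the evaluation region (default: all plate
    elements; pass :func:`bridging_span_mask` on a full construct to avoid
    the rigid-tie stress artifacts at the screw rims).
    """
    if element_mask is None:
        element_mask = mesh.region_mask("plate")
    sig = max_principal_stress(solution, mesh, materials, element_mask)
    sig = sig * load_scale
    passed = sig < strength
    failure_scale = math.inf if sig == 0 else strength / sig * load_scale
    return PatchStressReport(
        max_stress=float(sig),
        strength=float(strength),
        passed=bool(passed),
        utilization=float(sig / strength),
        failure_scale=float(failure_scale),
    )
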