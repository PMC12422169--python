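"""Parametric construct geometry: two tubular bone fragments, gap, plate, screws.

Coordinate convention (all lengths in mm):

* ``x`` — bone long axis, proximal -> distal, origin at the gap center;
* ``y`` — dorsal surface normal (the plate sits on the +y side);
* ``z`` — perpendicular to the sagittal (flexion) plane.

With this frame, sagittal-plane flexion of the distal fragment produces a
bending moment about ``z`` — the out-of-plane moment that is the primary
outcome of the internal-load analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = ["ConstructGeometry", "default_construct"]


@dataclass(frozen=True)
class ConstructGeometry:
    """Idealized plate-fixed mid-diaphyseal osteotomy construct.

    Bone fragments are straight tubes: a cortical shell of thickness
    ``cortical_thickness`` around a trabecular core.  The fragments are
    separated by an open transverse gap of ``gap_width`` centered at x = 0
    and bridged by a rectangular plate resting tangent to the dorsal
    surface, fixed by four bicortical screws.

    All dimensions in mm.
    """

    fragment_outer_radius: float = 4.5
    cortical_thickness: float = 1.5
    fragment_length: float = 25.0
    gap_width: float = 3.0
    plate_length: float = 24.25
    plate_width: float = 4.25
    plate_thickness: float = 1.0
    screw_offsets: tuple[float, ...] = (-10.0, -5.0, 5.0, 10.0)
    screw_diameter: float = 1.5

    def __post_init__(self) -> None:
        if self.gap_width <= 0:
            raise ValueError(f"gap_width must be positive, got {self.gap_width}")
        if self.cortical_thickness >= self.fragment_outer_radius:
            raise ValueError(
                "cortical_thickness must be smaller than fragment_outer_radius "
                f"({self.cortical_thickness} >= {self.fragment_outer_radius})"
            )
        offs = self.screw_offsets
        if self.plate_length <= 2.0 * max(abs(o) for o in offs):
            raise ValueError("plate must be longer than the outermost screw span")
        neg = sorted(-o for o in offs if o < 0)
        pos = sorted(o for o in offs if o > 0)
        if len(neg) != 2 or len(pos) != 2 or any(
            abs(a - b) > 1e-9 for a, b in zip(neg, pos)
        ):
            raise ValueError(
                "screw_offsets must be symmetric about 0 with two screws per side, "
                f"got {offs}"
            )
        for o in offs:
            if abs(o) <= self.gap_width / 2.0:
                raise ValueError(f"screw at x={o} lies inside the gap")

    # -- derived quantities -------------------------------------------------

    @property
    def inner_cortical_radius(self) -> float:
        return self.fragment_outer_radius - self.cortical_thickness

    @property
    def half_gap(self) -> float:
        return self.gap_width / 2.0

    @property
    def total_length(self) -> float:
        return 2.0 * self.fragment_length + self.gap_width

    @property
    def plate_bottom(self) -> float:
        """y of the plate underside (tangent plane on the dorsal surface)."""
        return self.fragment_outer_radius

    def fragment_span(self, side: str) -> tuple[float, float]:
        """Axial extent (x_min, x_max) of the proximal or distal fragment."""
        if side == "proximal":
            return (-self.half_gap - self.fragment_length, -self.half_gap)
        if side == "distal":
            return (self.half_gap, self.half_gap + self.fragment_length)
        raise ValueError(f"side must be 'proximal' or 'distal', got {side!r}")

    def with_overrides(self, **kwargs) -> "ConstructGeometry":
        """Copy with selected fields replaced (validation re-runs)."""
        return replace(self, **kwargs)


def default_construct(**overrides) -> ConstructGeometry:
    """The reference construct: 3 mm gap, 24.25 x 4.25 mm plate, four
    bicortical screws 5 mm apart with the innermost 5 mm from gap center.

    Keyword overrides replace individual fields (e.g. ``plate_thickness=2.0``).
    """
    return ConstructGeometry(**overrides)
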