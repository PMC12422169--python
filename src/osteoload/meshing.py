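"""Quadratic-tetrahedral meshing of the plate-fixed osteotomy construct.

The mesher is a deterministic structured-to-tetrahedral subdivision: each
bone fragment is a cylindrical hex/wedge scaffold (radial x azimuthal x
axial), the plate a rectilinear hex scaffold, and every scaffold cell is
split into tetrahedra through its centroid with quad faces diagonalized by
the smallest global node id — a rule that triangulates shared faces
identically on both sides, so the mesh is conforming everywhere, including
at the azimuthal seam and the wedge ring on the bone axis.  Linear
tetrahedra are then promoted to 10-node (tet10) elements with mid-edge
nodes at edge midpoints.

Screw holes in the plate are volume-matched staircase holes: for each screw
the through-thickness cell columns nearest the screw axis are removed, the
removed count chosen so the removed volume equals the analytic hole volume
to within half a cell.  Screws themselves are not meshed — they are rigid
kinematic tie groups (:func:`assign_ties`).

Node ring radii are inflated by ``sqrt(h / sin h)`` (h the azimuthal step)
so that the polygonal cross-sections have exactly the analytic annulus
areas, making per-region volume conservation near-exact at any resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .geometry import ConstructGeometry

__all__ = [
    "MeshParams",
    "Mesh",
    "MaterialField",
    "mesh_construct",
    "assign_materials",
    "assign_ties",
    "check_convergence",
    "DEFAULT_MATERIALS",
    "REGIONS",
]

REGIONS = {"cortical": 0, "trabecular": 1, "plate": 2, "screw": 3}
_REGION_NAMES = {v: k for k, v in REGIONS.items()}

#: Homogeneous per-region (Young's modulus MPa, Poisson ratio) defaults:
#: cortical / trabecular bone at textbook values, PEEK plate, titanium screw.
DEFAULT_MATERIALS: dict[str, tuple[float, float]] = {
    "cortical": (15000.0, 0.3),
    "trabecular": (500.0, 0.3),
    "plate": (3600.0, 0.38),
    "screw": (110000.0, 0.3),
}

# tet10 edge numbering: midside node 4+i bisects corner pair _TET_EDGES[i]
_TET_EDGES = np.array([(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)])


@dataclass(frozen=True)
class MeshParams:
    """Edge-length targets (mm) for the structured mesher.

    ``scale_factor`` multiplies every edge-length target, allowing the
    reference resolution (0.25 mm in the refinement region around the
    plate, 1 mm elsewhere) to be coarsened uniformly for desk-scale runs.
    ``refinement_region`` is an axial interval (x_min, x_max); ``None``
    means the plate span expanded by ``refinement_margin``.
    """

    min_edge: float = 0.25
    max_edge: float = 1.0
    refinement_max_edge: float = 0.25
    refinement_region: tuple[float, float] | None = None
    refinement_margin: float = 2.0
    scale_factor: float = 4.0

    def __post_init__(self) -> None:
        if not (self.min_edge <= self.refinement_max_edge <= self.max_edge):
            raise ValueError(
                "require min_edge <= refinement_max_edge <= max_edge, got "
                f"{self.min_edge}, {self.refinement_max_edge}, {self.max_edge}"
            )
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    @property
    def h_refined(self) -> float:
        """Scaffold cell size honoring the refined edge target.

        Cell sides are the target / sqrt(2) so that face diagonals of the
        tetrahedralized scaffold also respect the edge-length bound.
        """
        return self.refinement_max_edge * self.scale_factor / math.sqrt(2.0)

    @property
    def h_coarse(self) -> float:
        return self.max_edge * self.scale_factor / math.sqrt(2.0)

    def refinement_interval(self, geometry: ConstructGeometry) -> tuple[float, float]:
        if self.refinement_region is not None:
            return self.refinement_region
        half = geometry.plate_length / 2.0 + self.refinement_margin
        return (-half, half)


@dataclass
class MaterialField:
    """Per-element isotropic elastic constants (MPa, dimensionless)."""

    young: np.ndarray
    poisson: np.ndarray
    density: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.young <= 0):
            raise ValueError("all Young's moduli must be positive")
        if np.any((self.poisson <= 0) | (self.poisson >= 0.5)):
            raise ValueError("Poisson ratios must lie in (0, 0.5)")


@dataclass
class Mesh:
    """Conforming 10-node tetrahedral mesh with region tags and node sets.

    ``elements[:, :4]`` are corner nodes, ``elements[:, 4:]`` mid-edge
    nodes following the (0,1),(1,2),(2,0),(0,3),(1,3),(2,3) edge order.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_region: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    info: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def region_mask(self, name: str) -> np.ndarray:
        return self.element_region == REGIONS[name]

    def element_volumes(self) -> np.ndarray:
        c = self.nodes[self.elements[:, :4]]
        return np.einsum(
            "ei,ei->e", np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0]), c[:, 3] - c[:, 0]
        ) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements[:, :4]].mean(axis=1)

    def region_volume(self, name: str) -> float:
        return float(self.element_volumes()[self.region_mask(name)].sum())

    def edge_lengths(self, region: str | None = None) -> np.ndarray:
        """Lengths of all corner-to-corner element edges (with repeats)."""
        els = self.elements if region is None else self.elements[self.region_mask(region)]
        c = self.nodes[els[:, :4]]
        e = c[:, _TET_EDGES[:, 1]] - c[:, _TET_EDGES[:, 0]]
        return np.linalg.norm(e, axis=2).ravel()

    def scaled_jacobians(self) -> np.ndarray:
        """Per-element scaled Jacobian: min over the 4 corners of
        sqrt(2) * 6V / (product of the three incident edge lengths); 1 for a
        regular tetrahedron, <= 0 for inverted elements."""
        c = self.nodes[self.elements[:, :4]]
        vol6 = 6.0 * math.sqrt(2.0) * self.element_volumes()
        q = np.full(self.n_elements, np.inf)
        for v in range(4):
            others = [o for o in range(4) if o != v]
            e = c[:, others] - c[:, v : v + 1]
            prod = np.prod(np.linalg.norm(e, axis=2), axis=1)
            q = np.minimum(q, np.abs(vol6) / prod)
        return q * np.sign(vol6)


class MeshingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# scaffold -> tetrahedra
# ---------------------------------------------------------------------------

# hex faces as local-vertex cycles, VTK corner order
_HEX_FACES = np.array(
    [[0, 1, 2, 3], [4, 7, 6, 5], [0, 4, 5, 1], [1, 5, 6, 2], [2, 6, 7, 3], [3, 7, 4, 0]]
)
# wedge: vertices (a0, b00, b01, a1, b10, b11); two triangular + three quad faces
_WEDGE_TRIS = np.array([[0, 1, 2], [3, 5, 4]])
_WEDGE_QUADS = np.array([[0, 1, 4, 3], [1, 2, 5, 4], [2, 0, 3, 5]])


def _fan_quads(quads: np.ndarray) -> np.ndarray:
    """Split quad cycles (Q, 4) into triangles (Q, 2, 3) along the diagonal
    through each quad's smallest global node id (conforming across cells)."""
    p = np.argmin(quads, axis=1)
    idx = (p[:, None] + np.arange(4)) % 4
    g = np.take_along_axis(quads, idx, axis=1)
    tris = np.empty((len(quads), 2, 3), dtype=quads.dtype)
    tris[:, 0] = g[:, [0, 1, 2]]
    tris[:, 1] = g[:, [0, 2, 3]]
    return tris


def _cells_to_tets(
    nodes: list[np.ndarray],
    hexes: np.ndarray,
    wedges: np.ndarray,
    hex_tags: np.ndarray,
    wedge_tags: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tetrahedralize hex/wedge cells via centroid + min-id face fans.

    ``nodes`` is a mutable list wrapping the coordinate array (appended with
    centroid nodes).  Returns (coords, tet4 connectivity, region tags).
    """
    coords = nodes[0]
    tets, tags = [], []
    for cells, faces_tri, faces_quad, cell_tags in (
        (hexes, None, _HEX_FACES, hex_tags),
        (wedges, _WEDGE_TRIS, _WEDGE_QUADS, wedge_tags),
    ):
        if len(cells) == 0:
            continue
        cen_ids = len(coords) + np.arange(len(cells))
        coords = np.vstack([coords, coords[cells].mean(axis=1)])
        tris = []
        if faces_tri is not None:
            tris.append(cells[:, faces_tri].reshape(len(cells), -1, 3))
        quads = cells[:, faces_quad].reshape(-1, 4)
        tris.append(_fan_quads(quads).reshape(len(cells), -1, 3))
        tris = np.concatenate(tris, axis=1)  # (C, F, 3)
        nf = tris.shape[1]
        t = np.concatenate(
            [tris, np.broadcast_to(cen_ids[:, None, None], (len(cells), nf, 1))], axis=2
        ).reshape(-1, 4)
        tets.append(t)
        tags.append(np.repeat(cell_tags, nf))
    tet4 = np.vstack(tets)
    tag = np.concatenate(tags)
    # orient: positive signed volume
    c = coords[tet4]
    vol = np.einsum(
        "ei,ei->e", np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0]), c[:, 3] - c[:, 0]
    )
    flip = vol < 0
    tet4[flip, 1], tet4[flip, 2] = tet4[flip, 2].copy(), tet4[flip, 1].copy()
    degenerate = np.abs(vol) < 1e-12
    if degenerate.any():
        raise MeshingError(f"{degenerate.sum()} degenerate tetrahedra produced")
    nodes[0] = coords
    return coords, tet4, tag


def _tet4_to_tet10(coords: np.ndarray, tet4: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pairs = tet4[:, _TET_EDGES].reshape(-1, 2)
    pairs.sort(axis=1)
    keys = pairs[:, 0].astype(np.int64) * len(coords) + pairs[:, 1]
    uniq, inv = np.unique(keys, return_inverse=True)
    a, b = uniq // len(coords), uniq % len(coords)
    mids = 0.5 * (coords[a] + coords[b])
    mid_ids = len(coords) + inv.reshape(len(tet4), 6)
    return np.vstack([coords, mids]), np.hstack([tet4, mid_ids])


# ---------------------------------------------------------------------------
# body scaffolds
# ---------------------------------------------------------------------------


def _segment(lo: float, hi: float, h: float, n_min: int = 1) -> np.ndarray:
    n = max(n_min, math.ceil((hi - lo) / h - 1e-9))
    return np.linspace(lo, hi, n + 1)


def _fragment_scaffold(
    geometry: ConstructGeometry, params: MeshParams, side: str, offset: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cylindrical hex/wedge scaffold of one bone fragment.

    Returns (coords, hexes, wedges, hex_region, wedge_region) with global
    node ids starting at ``offset``.
    """
    r_ic, r_out = geometry.inner_cortical_radius, geometry.fragment_outer_radius
    h_b = params.h_coarse
    # radial stations: trabecular core to r_ic, cortical shell to r_out
    r_core = _segment(0.0, r_ic, h_b, n_min=2)
    r_cort = _segment(r_ic, r_out, min(h_b, geometry.cortical_thickness), n_min=1)
    radii = np.concatenate([r_core, r_cort[1:]])
    n_core_cells = len(r_core) - 1
    n_theta = max(8, math.ceil(2.0 * math.pi * r_out / h_b))
    n_theta += n_theta % 2
    # equal-area inflation: polygon ring areas match the analytic circles
    h_t = 2.0 * math.pi / n_theta
    radii = radii * math.sqrt(h_t / math.sin(h_t))
    # axial stations, graded: refined near the plate, coarse toward the end;
    # cap far-field axial length at 3x the transverse cell size to bound
    # element anisotropy (quality floor)
    transverse = min(float(np.diff(radii).min()), h_t * radii[1])
    h_b = min(h_b, 3.0 * transverse)
    x0, x1 = geometry.fragment_span(side)
    ref_lo, ref_hi = params.refinement_interval(geometry)
    h_ax = params.h_refined
    if side == "proximal":
        x_split = min(max(ref_lo, x0 + 1e-9), x1)
        xs = np.concatenate(
            [_segment(x0, x_split, h_b)[:-1], _segment(x_split, x1, h_ax)]
        ) if x_split > x0 + 1e-9 else _segment(x0, x1, h_ax)
    else:
        x_split = max(min(ref_hi, x1 - 1e-9), x0)
        xs = np.concatenate(
            [_segment(x0, x_split, h_ax)[:-1], _segment(x_split, x1, h_b)]
        ) if x_split < x1 - 1e-9 else _segment(x0, x1, h_ax)
    thetas = np.arange(n_theta) * h_t
    nr, nt, nx = len(radii) - 1, n_theta, len(xs)  # radii[0] == 0 -> axis
    ring_r = radii[1:]
    # node layout: axis nodes (nx), then ring nodes (nr, nt, nx)
    axis_ids = offset + np.arange(nx)
    ring_ids = offset + nx + np.arange(nr * nt * nx).reshape(nr, nt, nx)
    cos_t, sin_t = np.cos(thetas), np.sin(thetas)
    axis_coords = np.column_stack([xs, np.zeros(nx), np.zeros(nx)])
    y = np.einsum("r,t->rt", ring_r, cos_t)  # +y dorsal at theta = 0
    z = np.einsum("r,t->rt", ring_r, sin_t)
    ring_coords = np.stack(
        [
            np.broadcast_to(xs, (nr, nt, nx)),
            np.broadcast_to(y[:, :, None], (nr, nt, nx)),
            np.broadcast_to(z[:, :, None], (nr, nt, nx)),
        ],
        axis=-1,
    ).reshape(-1, 3)
    coords = np.vstack([axis_coords, ring_coords])

    jj = np.arange(nt)
    jp = (jj + 1) % nt
    kk = np.arange(nx - 1)
    # wedges: axis ring
    a0 = np.broadcast_to(axis_ids[kk], (nt, nx - 1))
    a1 = np.broadcast_to(axis_ids[kk + 1], (nt, nx - 1))
    b00 = ring_ids[0][jj][:, kk]
    b01 = ring_ids[0][jp][:, kk]
    b10 = ring_ids[0][jj][:, kk + 1]
    b11 = ring_ids[0][jp][:, kk + 1]
    wedges = np.stack([a0, b00, b01, a1, b10, b11], axis=-1).reshape(-1, 6)
    # hexes: rings 1..nr-1 (cells between ring i and i+1)
    hex_list = []
    hex_reg = []
    for i in range(nr - 1):
        v000 = ring_ids[i][jj][:, kk]
        v100 = ring_ids[i + 1][jj][:, kk]
        v110 = ring_ids[i + 1][jp][:, kk]
        v010 = ring_ids[i][jp][:, kk]
        v001 = ring_ids[i][jj][:, kk + 1]
        v101 = ring_ids[i + 1][jj][:, kk + 1]
        v111 = ring_ids[i + 1][jp][:, kk + 1]
        v011 = ring_ids[i][jp][:, kk + 1]
        h = np.stack([v000, v100, v110, v010, v001, v101, v111, v011], axis=-1).reshape(-1, 8)
        hex_list.append(h)
        # cell between radial station i+1 and i+2 (1-based ring index i+1)
        region = REGIONS["trabecular"] if (i + 1) < n_core_cells else REGIONS["cortical"]
        hex_reg.append(np.full(len(h), region, dtype=np.int8))
    hexes = np.vstack(hex_list) if hex_list else np.empty((0, 8), dtype=int)
    hex_region = np.concatenate(hex_reg) if hex_reg else np.empty(0, dtype=np.int8)
    wedge_region = np.full(len(wedges), REGIONS["trabecular"], dtype=np.int8)
    return coords, hexes, wedges, hex_region, wedge_region


def _plate_scaffold(
    geometry: ConstructGeometry, params: MeshParams, offset: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Rectilinear plate scaffold with volume-matched staircase screw holes."""
    g = geometry
    h = params.h_refined
    xs = _segment(-g.plate_length / 2.0, g.plate_length / 2.0, h)
    zs = _segment(-g.plate_width / 2.0, g.plate_width / 2.0, h)
    ys = _segment(g.plate_bottom, g.plate_bottom + g.plate_thickness, h)
    nx, ny, nz = len(xs), len(ys), len(zs)
    ids = offset + np.arange(nx * ny * nz).reshape(nx, ny, nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    xc = 0.5 * (xs[:-1] + xs[1:])
    zc = 0.5 * (zs[:-1] + zs[1:])
    dx, dz = np.diff(xs).mean(), np.diff(zs).mean()
    keep = np.ones((nx - 1, nz - 1), dtype=bool)
    r_hole = g.screw_diameter / 2.0
    m = int(round(math.pi * r_hole**2 / (dx * dz)))
    for x_s in g.screw_offsets:
        if m == 0:
            break
        d2 = (xc[:, None] - x_s) ** 2 + (zc[None, :] - 0.0) ** 2
        order = np.argsort(d2, axis=None, kind="stable")
        removed = 0
        for flat in order:
            i, k = np.unravel_index(flat, d2.shape)
            if keep[i, k]:
                keep[i, k] = False
                removed += 1
                if removed >= m:
                    break
    ii, kk = np.nonzero(keep)
    jj = np.arange(ny - 1)
    I = np.repeat(ii, ny - 1)
    K = np.repeat(kk, ny - 1)
    J = np.tile(jj, len(ii))
    hexes = np.stack(
        [
            ids[I, J, K],
            ids[I + 1, J, K],
            ids[I + 1, J, K + 1],
            ids[I, J, K + 1],
            ids[I, J + 1, K],
            ids[I + 1, J + 1, K],
            ids[I + 1, J + 1, K + 1],
            ids[I, J + 1, K + 1],
        ],
        axis=-1,
    )
    info = {"plate_cell": (dx, float(np.diff(ys).mean()), dz), "hole_cells": m}
    region = np.full(len(hexes), REGIONS["plate"], dtype=np.int8)
    return coords, hexes, region, info


def mesh_box(
    size: Sequence[float],
    h: float,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    region: str = "plate",
    divisions: Sequence[int] | None = None,
) -> Mesh:
    """Tet10 mesh of an axis-aligned box (verification fixtures, plate-only
    oracles).  ``h`` is the scaffold cell size; ``divisions`` overrides the
    per-axis cell counts directly."""
    size = np.asarray(size, float)
    origin = np.asarray(origin, float)
    if divisions is None:
        divisions = [max(1, math.ceil(s / h - 1e-9)) for s in size]
    axes = [np.linspace(origin[i], origin[i] + size[i], divisions[i] + 1) for i in range(3)]
    nx, ny, nz = (len(a) for a in axes)
    ids = np.arange(nx * ny * nz).reshape(nx, ny, nz)
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    coords = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    I, J, K = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    hexes = np.stack(
        [
            ids[I, J, K],
            ids[I + 1, J, K],
            ids[I + 1, J, K + 1],
            ids[I, J, K + 1],
            ids[I, J + 1, K],
            ids[I + 1, J + 1, K],
            ids[I + 1, J + 1, K + 1],
            ids[I, J + 1, K + 1],
        ],
        axis=-1,
    )
    holder = [coords]
    tag = np.full(len(hexes), REGIONS[region], dtype=np.int8)
    coords, tet4, tags = _cells_to_tets(
        holder, hexes, np.empty((0, 6), dtype=int), tag, np.empty(0, dtype=np.int8)
    )
    coords, tet10 = _tet4_to_tet10(coords, tet4)
    return Mesh(
        nodes=coords,
        elements=tet10,
        element_region=tags,
        info={"h_refined": h, "h_coarse": h, "plate_cell": tuple(size / divisions)},
    )


def mesh_construct(geometry: ConstructGeometry, params: MeshParams | None = None) -> Mesh:
    """Mesh the full construct (both fragments + plate) into tet10 elements.

    The three bodies are meshed independently (they interact only through
    the screw tie groups, assigned separately by :func:`assign_ties`).
    Named node sets ``pin_support`` (proximal end face),
    ``applied_displacement`` (distal end face) and the two optical-marker
    surrogates are attached.
    """
    params = params or MeshParams()
    for name, value in (
        ("gap_width", geometry.gap_width),
        ("plate_thickness", geometry.plate_thickness),
        ("fragment_length", geometry.fragment_length),
    ):
        if value <= 0:
            raise MeshingError(f"degenerate geometry: {name} = {value}")

    bodies = []
    hexes_all, wedges_all, hreg_all, wreg_all = [], [], [], []
    offset = 0
    for side in ("proximal", "distal"):
        c, hx, wd, hr, wr = _fragment_scaffold(geometry, params, side, offset)
        bodies.append(c)
        hexes_all.append(hx)
        wedges_all.append(wd)
        hreg_all.append(hr)
        wreg_all.append(wr)
        offset += len(c)
    c, hx, reg, plate_info = _plate_scaffold(geometry, params, offset)
    bodies.append(c)
    hexes_all.append(hx)
    hreg_all.append(reg)
    offset += len(c)

    coords = np.vstack(bodies)
    holder = [coords]
    coords, tet4, tags = _cells_to_tets(
        holder,
        np.vstack(hexes_all),
        np.vstack(wedges_all) if wedges_all else np.empty((0, 6), dtype=int),
        np.concatenate(hreg_all),
        np.concatenate(wreg_all) if wreg_all else np.empty(0, dtype=np.int8),
    )
    coords, tet10 = _tet4_to_tet10(coords, tet4)

    mesh = Mesh(nodes=coords, elements=tet10, element_region=tags, info=plate_info)
    mesh.info["h_refined"] = params.h_refined
    mesh.info["h_coarse"] = params.h_coarse

    tol = 1e-6
    x = coords[:, 0]
    x_min = -geometry.half_gap - geometry.fragment_length
    x_max = geometry.half_gap + geometry.fragment_length
    bone_max_y = geometry.fragment_outer_radius * 1.1  # below plate underside + inflation
    is_bone = coords[:, 1] <= bone_max_y  # crude body split only for marker sets
    mesh.node_sets["pin_support"] = np.nonzero(np.abs(x - x_min) < tol)[0]
    mesh.node_sets["applied_displacement"] = np.nonzero(np.abs(x - x_max) < tol)[0]
    for name, x_m in (
        ("marker_proximal", -(geometry.half_gap + geometry.fragment_length / 2.0)),
        ("marker_distal", geometry.half_gap + geometry.fragment_length / 2.0),
    ):
        target = np.array([x_m, geometry.fragment_outer_radius, 0.0])
        cand = np.nonzero(is_bone)[0]
        d = np.linalg.norm(coords[cand] - target, axis=1)
        mesh.node_sets[name] = cand[[int(np.argmin(d))]]

    q = mesh.scaled_jacobians()
    if q.min() < 0.05:
        raise MeshingError(
            f"mesh quality failure: min scaled Jacobian {q.min():.3g} < 0.05"
        )
    return mesh


# ---------------------------------------------------------------------------
# materials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DensityLaw:
    """Power-law density -> modulus mapping E = a * rho^b for bone regions.

    ``a`` in MPa at rho = 1 g/cm^3.  Plate and screw regions take explicit
    (E, nu) values since they are not mineralized tissue.
    """

    a: float = 6850.0
    b: float = 1.49
    poisson: float = 0.3
    plate: tuple[float, float] = DEFAULT_MATERIALS["plate"]
    screw: tuple[float, float] = DEFAULT_MATERIALS["screw"]


def assign_materials(
    mesh: Mesh,
    spec: dict[str, tuple[float, float]] | DensityLaw = None,
    density: np.ndarray | float | None = None,
) -> MaterialField:
    """Assign per-element elastic constants.

    ``spec`` is either a homogeneous mapping region -> (E MPa, nu) covering
    every region present in the mesh, or a :class:`DensityLaw` applied to a
    per-element (or scalar) ``density`` in g/cm^3 for bone regions.
    """
    if spec is None:
        spec = DEFAULT_MATERIALS
    E = np.empty(mesh.n_elements)
    nu = np.empty(mesh.n_elements)
    rho_out = None
    if isinstance(spec, DensityLaw):
        if density is None:
            raise ValueError("DensityLaw requires a density field")
        rho = np.broadcast_to(np.asarray(density, dtype=float), (mesh.n_elements,))
        bone = mesh.region_mask("cortical") | mesh.region_mask("trabecular")
        E[bone] = spec.a * rho[bone] ** spec.b
        nu[bone] = spec.poisson
        for name, (e_val, nu_val) in (("plate", spec.plate), ("screw", spec.screw)):
            m = mesh.region_mask(name)
            E[m], nu[m] = e_val, nu_val
        rho_out = rho.copy()
    else:
        present = set(np.unique(mesh.element_region))
        missing = {_REGION_NAMES[c] for c in present} - set(spec)
        if missing:
            raise ValueError(f"material spec missing regions: {sorted(missing)}")
        for name, (e_val, nu_val) in spec.items():
            if name not in REGIONS:
                raise ValueError(f"unknown region {name!r}")
            m = mesh.region_mask(name)
            E[m], nu[m] = e_val, nu_val
    return MaterialField(young=E, poisson=nu, density=rho_out)


# ---------------------------------------------------------------------------
# screw tie groups
# ---------------------------------------------------------------------------


def assign_ties(mesh: Mesh, geometry: ConstructGeometry) -> list[np.ndarray]:
    """Define one rigid kinematic tie group per screw.

    Each group couples the bone nodes inside the (bicortical) screw
    cylinder with the plate nodes on the hole rim; the capture radius is
    the screw radius plus 0.75 of the local scaffold spacing so that at
    least one ring of nodes is always captured.  Groups are stored as node
    sets ``screw_tie_1`` .. ``screw_tie_k`` and returned in order.
    """
    coords = mesh.nodes
    plate_nodes_mask = np.zeros(mesh.n_nodes, dtype=bool)
    plate_els = mesh.elements[mesh.region_mask("plate")]
    plate_nodes_mask[plate_els.ravel()] = True
    bone_mask = np.zeros(mesh.n_nodes, dtype=bool)
    bone_els = mesh.elements[mesh.region_mask("cortical") | mesh.region_mask("trabecular")]
    bone_mask[bone_els.ravel()] = True

    r_screw = geometry.screw_diameter / 2.0
    offs = sorted(geometry.screw_offsets)
    min_spacing = min(b - a for a, b in zip(offs, offs[1:]))
    r_cap = 0.45 * min_spacing  # keep adjacent groups disjoint
    step = 0.25 * mesh.info["h_refined"]
    r_ic = geometry.inner_cortical_radius

    # drop any previous tie sets
    for k in list(mesh.node_sets):
        if k.startswith("screw_tie_"):
            del mesh.node_sets[k]

    def _capture(d_axis, mask, accept, what, idx):
        """Grow the capture radius from the screw radius until ``accept``."""
        r = r_screw + 1e-9
        while r <= r_cap:
            sel = np.nonzero(mask & (d_axis <= r))[0]
            if accept(sel):
                return sel
            r += step
        raise MeshingError(
            f"tie group {idx}: could not capture a valid {what} node set "
            f"within radius {r_cap:.2f} mm (mesh too coarse near screw)"
        )

    groups = []
    for idx, x_s in enumerate(geometry.screw_offsets, start=1):
        if abs(x_s) > geometry.half_gap + geometry.fragment_length or abs(
            x_s
        ) > geometry.plate_length / 2.0:
            raise ValueError(f"screw at x={x_s} lies outside bone or plate")
        d_axis = np.hypot(coords[:, 0] - x_s, coords[:, 2])

        def bicortical(sel):
            if len(sel) < 12:
                return False
            y = coords[sel, 1]
            return y.max() >= r_ic and y.min() <= -r_ic

        bone_sel = _capture(d_axis, bone_mask, bicortical, "bicortical bone", idx)
        plate_sel = _capture(
            d_axis, plate_nodes_mask, lambda s: len(s) >= 8, "plate hole rim", idx
        )
        group = np.concatenate([bone_sel, plate_sel])
        mesh.node_sets[f"screw_tie_{idx}"] = group
        groups.append(group)
    return groups


# ---------------------------------------------------------------------------
# convergence study
# ---------------------------------------------------------------------------


def check_convergence(
    geometry: ConstructGeometry,
    params_sequence: Sequence[MeshParams],
    pipeline: Callable[[ConstructGeometry, MeshParams], float],
    criterion: float = 0.05,
) -> dict:
    """Run ``pipeline`` (mesh -> solve -> section moment) over successive
    refinements and report relative moment changes between levels.

    Returns ``{"moments": [...], "relative_changes": [...], "converged":
    bool}`` where ``relative_changes[i] = |M_i - M_{i+1}| / |M_{i+1}|`` and
    convergence requires the final change below ``criterion`` (default the
    5% bending-moment criterion).
    """
    if len(params_sequence) < 2:
        raise ValueError("need >=2 refinement levels")
    moments = [float(pipeline(geometry, p)) for p in params_sequence]
    rel = [
        abs(a - b) / abs(b) if b != 0 else math.inf
        for a, b in zip(moments, moments[1:])
    ]
    return {
        "moments": moments,
        "relative_changes": rel,
        "converged": rel[-1] < criterion,
    }
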