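"""Small-strain linear-elastic FE solver for 10-node tetrahedra.

Displacement-driven: boundary conditions are a pinned node set (all
translations fixed), a prescribed-displacement node set, and rigid
kinematic tie groups (6 degrees of freedom each) representing the screws.
Ties are eliminated master–slave style — every tie node's displacement is
expressed through its group's rigid-body translation and (linearized)
rotation, so there are no penalty or Lagrange parameters.

Stiffness integration uses the standard 4-point Gauss rule, which is exact
for the quadratic (constant-to-linear strain) fields of straight-edged
tet10 elements; the patch test is reproduced to machine precision.
Units: mm / N / MPa throughout, so moments are N·mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .meshing import MaterialField, Mesh

__all__ = [
    "BoundaryConditions",
    "SolutionField",
    "assemble",
    "solve",
    "element_stresses",
    "internal_forces",
    "max_principal_stress",
]

# 4-point Gauss rule on the reference tetrahedron (barycentric perms)
_GA, _GB = 0.5854101966249685, 0.13819660112501053
_GPOINTS = np.array(
    [
        [_GA, _GB, _GB],
        [_GB, _GA, _GB],
        [_GB, _GB, _GA],
        [_GB, _GB, _GB],
    ]
)

# corner nodes 0..3 carry barycentric L1..L4 (L4 = 1 - L1 - L2 - L3);
# midside node 4+i bisects edge pair (see meshing._TET_EDGES)
_EDGE_PAIRS = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]


def _shape_gradients(points: np.ndarray) -> np.ndarray:
    """dN/dxi for the 10 tet10 shape functions at given (L1,L2,L3) points.

    Returns an array of shape (n_points, 10, 3).
    """
    points = np.atleast_2d(points)
    n = len(points)
    grads = np.zeros((n, 10, 3))
    L = np.zeros((n, 4))
    L[:, :3] = points
    L[:, 3] = 1.0 - points.sum(axis=1)
    # dL_a/dxi_k: identity for a<3, -1 for L4
    dL = np.vstack([np.eye(3), -np.ones((1, 3))])  # (4, 3)
    for a in range(4):
        # corner N_a = L_a (2 L_a - 1)
        grads[:, a, :] = (4.0 * L[:, a : a + 1] - 1.0) * dL[a]
    for e, (a, b) in enumerate(_EDGE_PAIRS):
        grads[:, 4 + e, :] = 4.0 * (L[:, a : a + 1] * dL[b] + L[:, b : b + 1] * dL[a])
    return grads


_GP_GRADS = _shape_gradients(_GPOINTS)  # (4, 10, 3)

# nodal barycentric coordinates (for stress recovery at element nodes)
_NODE_XI = np.array(
    [
        [1, 0, 0],
        [0, 1, 0],
        [0, 0, 1],
        [0, 0, 0],
        [0.5, 0.5, 0],
        [0, 0.5, 0.5],
        [0.5, 0, 0.5],
        [0.5, 0, 0],
        [0, 0.5, 0],
        [0, 0, 0.5],
    ],
    dtype=float,
)
_NODE_GRADS = _shape_gradients(_NODE_XI)  # (10, 10, 3)


class SolverError(RuntimeError):
    pass


def _jacobians(coords: np.ndarray, els: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Affine Jacobians J (E,3,3) and detJ (E,) for straight tet10s."""
    c = coords[els[:, :4]]
    J = np.stack([c[:, 0] - c[:, 3], c[:, 1] - c[:, 3], c[:, 2] - c[:, 3]], axis=2)
    # the (0,1,2;3) corner convention makes det J = -6V for a positively
    # oriented tet; report the volume-consistent 6V
    det6V = -np.linalg.det(J)
    return J, det6V


def _grad_operators(
    coords: np.ndarray, els: np.ndarray, points_grads: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Physical shape-function gradients at evaluation points.

    Returns (G, detJ): G has shape (E, n_points, 10, 3).
    """
    J, detJ = _jacobians(coords, els)
    bad = np.nonzero(detJ <= 0)[0]
    if len(bad):
        raise SolverError(f"degenerate element(s) with non-positive Jacobian: {bad[:5]}")
    Jinv = np.linalg.inv(J)
    G = np.einsum("pna,eab->epnb", points_grads, Jinv)
    return G, detJ


def _stiffness_batch(
    coords: np.ndarray, els: np.ndarray, E: np.ndarray, nu: np.ndarray
) -> np.ndarray:
    """Element stiffness matrices (B, 30, 30), DOFs node-major (n*3 + i)."""
    G, detJ = _grad_operators(coords, els, _GP_GRADS)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    w = detJ / 24.0  # four equal-weight points, reference volume 1/6
    T1 = np.einsum("e,egni,egmj->enimj", w, G, G, optimize=True)
    tr = np.einsum("enkmk->enm", T1)
    K = lam[:, None, None, None, None] * T1
    K += mu[:, None, None, None, None] * T1.transpose(0, 1, 4, 3, 2)
    eye = np.eye(3)
    K += mu[:, None, None, None, None] * np.einsum("enm,ij->enimj", tr, eye)
    return K.reshape(len(els), 30, 30)


def assemble(mesh: Mesh, materials: MaterialField, batch: int = 4096) -> sp.csr_matrix:
    """Assemble the global stiffness operator (sparse CSR, symmetric PSD).

    Before constraints the operator's null space is spanned by the six
    rigid-body modes of each disconnected body.
    """
    n_dof = 3 * mesh.n_nodes
    K = sp.csr_matrix((n_dof, n_dof))
    for start in range(0, mesh.n_elements, batch):
        els = mesh.elements[start : start + batch]
        Ke = _stiffness_batch(
            mesh.nodes,
            els,
            materials.young[start : start + batch],
            materials.poisson[start : start + batch],
        )
        dofs = (3 * els[:, :, None] + np.arange(3)).reshape(len(els), 30)
        rows = np.repeat(dofs, 30, axis=1).ravel()
        cols = np.tile(dofs, (1, 30)).ravel()
        K = K + sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n_dof, n_dof)).tocsr()
    return K


def internal_forces(
    mesh: Mesh,
    materials: MaterialField,
    displacements: np.ndarray,
    element_ids: np.ndarray,
    batch: int = 4096,
) -> np.ndarray:
    """Nodal internal forces sum(K_e u_e) over a subset of elements, (N, 3)."""
    f = np.zeros((mesh.n_nodes, 3))
    u = displacements.ravel()
    for start in range(0, len(element_ids), batch):
        ids = element_ids[start : start + batch]
        els = mesh.elements[ids]
        Ke = _stiffness_batch(
            mesh.nodes, els, materials.young[ids], materials.poisson[ids]
        )
        dofs = (3 * els[:, :, None] + np.arange(3)).reshape(len(els), 30)
        fe = np.einsum("eab,eb->ea", Ke, u[dofs])
        np.add.at(f.ravel(), dofs.ravel(), fe.ravel())
    return f


# ---------------------------------------------------------------------------
# boundary conditions & solve
# ---------------------------------------------------------------------------


@dataclass
class BoundaryConditions:
    """Dirichlet data and rigid tie groups.

    ``prescribed_values`` holds one displacement vector per node in
    ``prescribed`` (mm).  ``pinned`` nodes have all translations fixed.
    Tie groups are node-id arrays; each group moves as a 6-DOF rigid body.
    """

    pinned: np.ndarray
    prescribed: np.ndarray
    prescribed_values: np.ndarray
    tie_groups: list[np.ndarray] = field(default_factory=list)
    prescribed_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pinned = np.asarray(self.pinned, dtype=int)
        self.prescribed = np.asarray(self.prescribed, dtype=int)
        self.prescribed_values = np.atleast_2d(np.asarray(self.prescribed_values, float))
        if self.prescribed_values.shape == (1, 3) and len(self.prescribed) > 1:
            self.prescribed_values = np.broadcast_to(
                self.prescribed_values, (len(self.prescribed), 3)
            ).copy()
        if len(self.prescribed_values) != len(self.prescribed):
            raise ValueError("one prescribed displacement vector per node required")
        if not np.all(np.isfinite(self.prescribed_values)):
            raise ValueError("prescribed displacements must be finite")
        if np.intersect1d(self.pinned, self.prescribed).size:
            raise ValueError("pinned and prescribed node sets must be disjoint")
        if self.prescribed_mask is None:
            self.prescribed_mask = np.ones_like(self.prescribed_values, dtype=bool)
        else:
            self.prescribed_mask = np.broadcast_to(
                np.atleast_2d(np.asarray(self.prescribed_mask, bool)),
                self.prescribed_values.shape,
            ).copy()


@dataclass
class SolutionField:
    """Nodal displacements (mm) plus reactions (N) from the solved system.

    ``reactions`` is K·u: zero (to solver tolerance) on unconstrained free
    nodes, the support/driving reactions on Dirichlet nodes, and the
    equal-and-opposite coupling forces within tie groups.
    """

    displacements: np.ndarray
    reactions: np.ndarray
    residual: float
    constrained: np.ndarray

    def total_reaction(self, nodes: np.ndarray) -> np.ndarray:
        return self.reactions[nodes].sum(axis=0)


def _tie_transform(
    n_nodes: int, tie_groups: Sequence[np.ndarray], coords: np.ndarray
) -> tuple[sp.csr_matrix, np.ndarray, int]:
    """Master–slave reduction matrix T (3N x n_reduced).

    Free nodes keep their 3 DOFs; each tie group is replaced by a rigid
    translation t and linearized rotation theta:  u_i = t + theta x r_i.
    Returns (T, node_reduced_offset, n_reduced); tie nodes get offset -1-g.
    """
    owner = np.full(n_nodes, -1, dtype=int)
    for g, grp in enumerate(tie_groups):
        if np.any(owner[grp] >= 0) or len(np.unique(grp)) != len(grp):
            raise ValueError("tie groups must be disjoint")
        owner[grp] = g
    free = np.nonzero(owner < 0)[0]
    n_red = 3 * len(free) + 6 * len(tie_groups)
    red_of_free = np.full(n_nodes, -1, dtype=int)
    red_of_free[free] = 3 * np.arange(len(free))
    rows, cols, vals = [], [], []
    # identity block for free nodes
    fdof = (3 * free[:, None] + np.arange(3)).ravel()
    rdof = (red_of_free[free][:, None] + np.arange(3)).ravel()
    rows.append(fdof)
    cols.append(rdof)
    vals.append(np.ones(len(fdof)))
    base = 3 * len(free)
    for g, grp in enumerate(tie_groups):
        c = coords[grp].mean(axis=0)
        r = coords[grp] - c
        gbase = base + 6 * g
        for i in range(3):  # u_i = t_i + (theta x r)_i
            rows.append(3 * grp + i)
            cols.append(np.full(len(grp), gbase + i))
            vals.append(np.ones(len(grp)))
        # theta x r = (ty*rz - tz*ry, tz*rx - tx*rz, tx*ry - ty*rx)
        cross = [
            (0, 4, r[:, 2]),
            (0, 5, -r[:, 1]),
            (1, 5, r[:, 0]),
            (1, 3, -r[:, 2]),
            (2, 3, r[:, 1]),
            (2, 4, -r[:, 0]),
        ]
        for i, j, v in cross:
            rows.append(3 * grp + i)
            cols.append(np.full(len(grp), gbase + j))
            vals.append(v)
    T = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n_nodes, n_red),
    ).tocsr()
    return T, red_of_free, n_red


def solve(
    stiffness: sp.spmatrix, bcs: BoundaryConditions, nodes: np.ndarray
) -> SolutionField:
    """Solve K u = 0 under Dirichlet data and rigid ties.

    Direct sparse factorization (SuperLU).  Constrained DOFs match their
    imposed values exactly; the free-DOF residual is checked against a
    1e-8 relative tolerance (one step of iterative refinement if needed).
    """
    n_nodes = len(nodes)
    K = stiffness.tocsr()
    for grp in bcs.tie_groups:
        clash = np.intersect1d(grp, np.concatenate([bcs.pinned, bcs.prescribed]))
        if clash.size:
            raise ValueError(f"tie group overlaps Dirichlet nodes: {clash[:5]}")
    T, red_of_free, n_red = _tie_transform(n_nodes, bcs.tie_groups, nodes)
    Kr = (T.T @ K @ T).tocsr()

    known_nodes = np.concatenate([bcs.pinned, bcs.prescribed])
    if np.any(red_of_free[known_nodes] < 0):
        raise ValueError("Dirichlet nodes may not belong to tie groups")
    n_constrained = 3 * len(bcs.pinned) + int(
        bcs.prescribed_mask.sum() if len(bcs.prescribed) else 0
    )
    if n_constrained < 6:
        raise SolverError(
            "under-constrained system: "
            f"{n_constrained} constrained DOFs cannot remove the 6 rigid-body "
            "modes (translations and rotations remain)"
        )
    comp_mask = np.vstack(
        [np.ones((len(bcs.pinned), 3), dtype=bool), bcs.prescribed_mask]
    ).ravel()
    known_red = (red_of_free[known_nodes][:, None] + np.arange(3)).ravel()[comp_mask]
    known_vals = np.vstack(
        [np.zeros((len(bcs.pinned), 3)), bcs.prescribed_values]
    ).ravel()[comp_mask]
    mask = np.ones(n_red, dtype=bool)
    mask[known_red] = False
    free_red = np.nonzero(mask)[0]

    Kuu = Kr[free_red][:, free_red].tocsc()
    Kuk = Kr[free_red][:, known_red]
    rhs = -Kuk @ known_vals
    try:
        lu = splu(Kuu)
    except RuntimeError as exc:  # singular => rigid modes remain
        raise SolverError(
            "under-constrained system: rigid-body modes remain after applying "
            f"boundary conditions ({exc})"
        ) from exc
    qu = lu.solve(rhs)
    res = Kuu @ qu - rhs
    scale = max(np.abs(rhs).max(), 1e-30)
    if np.abs(res).max() > 1e-8 * scale:
        qu = qu + lu.solve(-res)
        res = Kuu @ qu - rhs
    residual = float(np.abs(res).max() / scale)
    if not np.isfinite(qu).all() or residual > 1e-6:
        raise SolverError(
            f"solver failed to converge (relative residual {residual:.2e}); "
            "system may be under-constrained"
        )
    q = np.empty(n_red)
    q[free_red] = qu
    q[known_red] = known_vals
    u = (T @ q).reshape(n_nodes, 3)
    reactions = (K @ u.ravel()).reshape(n_nodes, 3)
    return SolutionField(
        displacements=u,
        reactions=reactions,
        residual=residual,
        constrained=known_nodes,
    )


# ---------------------------------------------------------------------------
# stress recovery
# ---------------------------------------------------------------------------


def _stresses_at(
    mesh: Mesh,
    materials: MaterialField,
    displacements: np.ndarray,
    point_grads: np.ndarray,
    batch: int = 4096,
) -> np.ndarray:
    """Stress tensors (Voigt xx,yy,zz,xy,yz,xz) at reference points."""
    npts = point_grads.shape[0]
    out = np.empty((mesh.n_elements, npts, 6))
    u = displacements.reshape(-1, 3)
    lam_all = materials.young * materials.poisson / (
        (1 + materials.poisson) * (1 - 2 * materials.poisson)
    )
    mu_all = materials.young / (2 * (1 + materials.poisson))
    for start in range(0, mesh.n_elements, batch):
        els = mesh.elements[start : start + batch]
        G, _ = _grad_operators(mesh.nodes, els, point_grads)
        ue = u[els]  # (E, 10, 3)
        grad_u = np.einsum("epni,enj->epij", G, ue)  # du_j/dx_i
        eps = 0.5 * (grad_u + grad_u.transpose(0, 1, 3, 2))
        lam = lam_all[start : start + batch, None]
        mu = mu_all[start : start + batch, None]
        trace = np.einsum("epii->ep", eps)
        sig = 2.0 * mu[..., None, None] * eps
        sig[:, :, 0, 0] += lam * trace
        sig[:, :, 1, 1] += lam * trace
        sig[:, :, 2, 2] += lam * trace
        out[start : start + batch, :, 0] = sig[:, :, 0, 0]
        out[start : start + batch, :, 1] = sig[:, :, 1, 1]
        out[start : start + batch, :, 2] = sig[:, :, 2, 2]
        out[start : start + batch, :, 3] = sig[:, :, 0, 1]
        out[start : start + batch, :, 4] = sig[:, :, 1, 2]
        out[start : start + batch, :, 5] = sig[:, :, 0, 2]
    return out


def element_stresses(
    solution: SolutionField, mesh: Mesh, materials: MaterialField
) -> np.ndarray:
    """Per-element stress tensors at the 4 Gauss points, shape (E, 4, 6)."""
    return _stresses_at(mesh, materials, solution.displacements, _GP_GRADS)


def max_principal_stress(
    solution: SolutionField,
    mesh: Mesh,
    materials: MaterialField,
    element_mask: np.ndarray | None = None,
) -> float:
    """Maximum principal stress over elements, evaluated at element nodes
    (captures extreme-fiber values that interior Gauss points miss)."""
    sig = _stresses_at(mesh, materials, solution.displacements, _NODE_GRADS)
    if element_mask is not None:
        sig = sig[element_mask]
    S = np.empty(sig.shape[:2] + (3, 3))
    S[..., 0, 0], S[..., 1, 1], S[..., 2, 2] = sig[..., 0], sig[..., 1], sig[..., 2]
    S[..., 0, 1] = S[..., 1, 0] = sig[..., 3]
    S[..., 1, 2] = S[..., 2, 1] = sig[..., 4]
    S[..., 0, 2] = S[..., 2, 0] = sig[..., 5]
    eig = np.linalg.eigvalsh(S.reshape(-1, 3, 3))
    return float(eig[:, 2].max())
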