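import numpy as np
import pytest

from osteoload import (
    BoundaryConditions,
    assemble,
    assign_materials,
    element_stresses,
    mesh_box,
    solve,
)
from osteoload.meshing import _TET_EDGES
from osteoload.solver import SolverError, _stiffness_batch, internal_forces


@pytest.fixture(scope="module")
def cube():
    mesh = mesh_box([1.0, 1.0, 1.0], 0.5)
    mat = assign_materials(mesh, {"plate": (200.0, 0.3)})
    return mesh, mat, assemble(mesh, mat)


def _boundary(mesh):
    x = mesh.nodes
    on = np.zeros(len(x), bool)
    for ax in range(3):
        on |= np.abs(x[:, ax]) < 1e-9
        on |= np.abs(x[:, ax] - 1.0) < 1e-9
    return np.nonzero(on)[0]


class TestElementAndAssembly:
    def test_single_tet10_symmetric(self):
        corners = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        coords = np.vstack(
            [corners, 0.5 * (corners[_TET_EDGES[:, 0]] + corners[_TET_EDGES[:, 1]])]
        )
        Ke = _stiffness_batch(coords, np.arange(10)[None], np.array([1e3]), np.array([0.3]))[0]
        assert Ke.shape == (30, 30)
        assert np.abs(Ke - Ke.T).max() <= 1e-10 * np.abs(Ke).max()

    def test_rigid_body_modes_in_null_space(self):
        corners = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        coords = np.vstack(
            [corners, 0.5 * (corners[_TET_EDGES[:, 0]] + corners[_TET_EDGES[:, 1]])]
        )
        Ke = _stiffness_batch(coords, np.arange(10)[None], np.array([1e3]), np.array([0.3]))[0]
        scale = np.abs(Ke).max()
        for t in np.eye(3):  # translations
            u = np.tile(t, 10)
            assert np.abs(Ke @ u).max() <= 1e-12 * scale
        for axis in np.eye(3):  # linearized rotations
            u = np.cross(np.broadcast_to(axis, (10, 3)), coords).ravel()
            assert np.abs(Ke @ u).max() <= 1e-12 * scale

    def test_global_operator_symmetric(self, cube):
        _, _, K = cube
        assert abs(K - K.T).max() <= 1e-10

    def test_assembly_invariant_under_region_split(self):
        mesh = mesh_box([1.0, 1.0, 1.0], 0.5, region="plate")
        mat1 = assign_materials(mesh, {"plate": (123.0, 0.25)})
        # same constants delivered through a two-region tagging
        half = mesh.element_centroids()[:, 0] > 0.5
        mesh.element_region[half] = 0  # cortical code
        mat2 = assign_materials(
            mesh, {"plate": (123.0, 0.25), "cortical": (123.0, 0.25)}
        )
        K1, K2 = assemble(mesh, mat1), assemble(mesh, mat2)
        assert abs(K1 - K2).max() <= 1e-12


class TestSolve:
    def test_zero_prescription_zero_solution(self, cube):
        mesh, mat, K = cube
        bnd = _boundary(mesh)
        bcs = BoundaryConditions(
            pinned=bnd, prescribed=np.array([], int), prescribed_values=np.zeros((0, 3))
        )
        sol = solve(K, bcs, mesh.nodes)
        assert np.abs(sol.displacements).max() == 0.0
        assert np.abs(sol.reactions).max() <= 1e-12

    def test_patch_test_exact(self, cube):
        """tet10 reproduces an arbitrary linear displacement field exactly
        when it is imposed on the boundary."""
        mesh, mat, K = cube
        A = np.array([[0.01, 0.002, -0.001], [0.003, -0.004, 0.0], [0.0, 0.001, 0.005]])
        uex = mesh.nodes @ A.T
        bnd = _boundary(mesh)
        bcs = BoundaryConditions(
            pinned=np.array([], int), prescribed=bnd, prescribed_values=uex[bnd]
        )
        sol = solve(K, bcs, mesh.nodes)
        assert np.abs(sol.displacements - uex).max() <= 1e-10

    def test_patch_stress_uniform(self, cube):
        mesh, mat, K = cube
        eps = 0.01
        uex = np.column_stack(
            [eps * mesh.nodes[:, 0], -0.003 * mesh.nodes[:, 1], -0.003 * mesh.nodes[:, 2]]
        )
        bnd = _boundary(mesh)
        bcs = BoundaryConditions(
            pinned=np.array([], int), prescribed=bnd, prescribed_values=uex[bnd]
        )
        sol = solve(K, bcs, mesh.nodes)
        sig = element_stresses(sol, mesh, mat)
        assert sig.std(axis=(0, 1)).max() <= 1e-10
        E, nu = 200.0, 0.3
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        tr = 0.01 - 0.003 - 0.003
        assert sig[:, :, 0].mean() == pytest.approx(lam * tr + 2 * mu * eps, rel=1e-10)

    def test_under_constrained_reported(self, cube):
        mesh, mat, K = cube
        one = np.array([0])
        bcs = BoundaryConditions(
            pinned=one, prescribed=np.array([], int), prescribed_values=np.zeros((0, 3))
        )
        with pytest.raises(SolverError):
            solve(K, bcs, mesh.nodes)

    def test_linearity_and_superposition(self, cube):
        mesh, mat, K = cube
        x = mesh.nodes
        lo = np.nonzero(np.abs(x[:, 0]) < 1e-9)[0]
        hi = np.nonzero(np.abs(x[:, 0] - 1) < 1e-9)[0]

        def stretch(d):
            bcs = BoundaryConditions(
                pinned=lo, prescribed=hi, prescribed_values=np.tile(d, (len(hi), 1))
            )
            return solve(K, bcs, mesh.nodes).displacements

        ua = stretch([0.02, 0.0, 0.0])
        ub = stretch([0.0, 0.01, 0.0])
        uab = stretch([0.02, 0.01, 0.0])
        assert np.abs(2 * ua - stretch([0.04, 0.0, 0.0])).max() <= 1e-10
        assert np.abs(ua + ub - uab).max() <= 1e-8

    def test_tie_group_moves_rigidly(self, cube):
        mesh, mat, K = cube
        x = mesh.nodes
        lo = np.nonzero(np.abs(x[:, 0]) < 1e-9)[0]
        hi = np.nonzero(np.abs(x[:, 0] - 1) < 1e-9)[0]
        mid = np.nonzero(np.abs(x[:, 0] - 0.5) < 1e-9)[0]
        bcs = BoundaryConditions(
            pinned=lo, prescribed=hi,
            prescribed_values=np.tile([0.0, 0.05, 0.0], (len(hi), 1)),
            tie_groups=[mid],
        )
        sol = solve(K, bcs, mesh.nodes)
        # best-fit rigid motion must reproduce tie-node displacements exactly
        u = sol.displacements[mid]
        c = x[mid].mean(axis=0)
        r = x[mid] - c
        t = u.mean(axis=0)
        # linearized rotation from least squares
        A = np.zeros((3, 3))
        b = np.zeros(3)
        for ri, ui in zip(r, u - t):
            Rx = np.array([[0, ri[2], -ri[1]], [-ri[2], 0, ri[0]], [ri[1], -ri[0], 0]])
            A += Rx.T @ Rx
            b += Rx.T @ ui
        theta = np.linalg.solve(A, b)
        fit = t + np.cross(np.broadcast_to(theta, r.shape), r)
        assert np.abs(u - fit).max() <= 1e-10


class TestCantileverOracle:
    def test_tip_reaction_matches_beam_theory(self, cantilever):
        c = cantilever
        P = c["solution"].reactions[c["tip"], 1].sum()
        P_ref = 3 * c["E"] * c["I"] * c["delta"] / c["L"] ** 3
        assert P == pytest.approx(P_ref, rel=0.05)

    def test_global_equilibrium(self, cantilever):
        c = cantilever
        R = c["solution"].reactions
        scale = np.abs(R).max()
        assert np.abs(R.sum(axis=0)).max() <= 1e-8 * scale
        M = np.cross(c["mesh"].nodes, R).sum(axis=0)
        assert np.abs(M).max() <= 1e-8 * scale * c["L"]

    def test_beam_error_decreases_under_refinement(self):
        from osteoload import assemble as _assemble

        L, W, t, E, nu, delta = 24.25, 4.25, 1.0, 3600.0, 0.38, 0.1
        errors = []
        for h in (1.6, 1.1, 0.7):
            mesh = mesh_box([L, t, W], h, origin=(0.0, 4.5, -W / 2))
            mat = assign_materials(mesh, {"plate": (E, nu)})
            K = _assemble(mesh, mat)
            x = mesh.nodes
            root = np.nonzero(np.abs(x[:, 0]) < 1e-9)[0]
            tip = np.nonzero(np.abs(x[:, 0] - L) < 1e-9)[0]
            bcs = BoundaryConditions(
                pinned=root, prescribed=tip,
                prescribed_values=np.tile([0.0, delta, 0.0], (len(tip), 1)),
                prescribed_mask=np.tile([False, True, False], (len(tip), 1)),
            )
            sol = solve(K, bcs, mesh.nodes)
            P = sol.reactions[tip, 1].sum()
            P_ref = 3 * E * (W * t**3 / 12) * delta / L**3
            errors.append(abs(P / P_ref - 1))
        assert errors[0] >= errors[1] >= errors[2]
        assert errors[-1] < 0.05

    def test_bending_stress_profile_linear_through_thickness(self, cantilever):
        """Extreme-fiber axial stress near the root matches M*c/I."""
        c = cantilever
        mesh, mat, sol = c["mesh"], c["materials"], c["solution"]
        P = sol.reactions[c["tip"], 1].sum()
        x0 = c["L"] / 2
        M = P * (c["L"] - x0)
        sig = element_stresses(sol, mesh, mat)
        cent = mesh.element_centroids()
        band = np.abs(cent[:, 0] - x0) < 0.75
        y = 4.5 + c["t"] / 2 - cent[band, 1]  # fiber distance from mid-plane
        sxx = sig[band, :, 0].mean(axis=1)
        # linear fit sigma_xx vs fiber coordinate
        slope = np.polyfit(y, sxx, 1)[0]
        slope_ref = M / c["I"]
        assert slope == pytest.approx(slope_ref, rel=0.05)


def test_internal_forces_sum_to_zero_on_free_interior(cube):
    mesh, mat, K = cube
    x = mesh.nodes
    lo = np.nonzero(np.abs(x[:, 0]) < 1e-9)[0]
    hi = np.nonzero(np.abs(x[:, 0] - 1) < 1e-9)[0]
    bcs = BoundaryConditions(
        pinned=lo, prescribed=hi, prescribed_values=np.tile([0.01, 0, 0], (len(hi), 1))
    )
    sol = solve(K, bcs, mesh.nodes)
    f = internal_forces(mesh, mat, sol.displacements, np.arange(mesh.n_elements))
    free = np.setdiff1d(np.arange(mesh.n_nodes), np.concatenate([lo, hi]))
    assert np.abs(f[free]).max() <= 1e-8 * np.abs(f).max()
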