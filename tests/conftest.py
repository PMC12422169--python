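"""Shared fixtures: small FE models solved once per session.

FE solves are the expensive part of the suite, so constructs are meshed at
deliberately coarse desk-scale resolutions here; resolution-sensitive
oracle checks (cantilever vs beam theory, mesh convergence) use their own
meshes sized for the tolerance they assert.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from osteoload import (
    BoundaryConditions,
    MeshParams,
    assemble,
    assign_materials,
    build_model,
    default_construct,
    mesh_box,
    solve,
    unit_section_loads,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry():
    return default_construct()


@pytest.fixture(scope="session")
def tiny_model(geometry):
    """Very coarse construct model (fast linearity/BC checks)."""
    return build_model(geometry, MeshParams(scale_factor=16.0))


@pytest.fixture(scope="session")
def coarse_model(geometry):
    """Moderate construct model for section-load and pipeline checks."""
    return build_model(geometry, MeshParams(scale_factor=8.0))


@pytest.fixture(scope="session")
def coarse_state(coarse_model):
    """Unit-amplitude flexion solve of the coarse model: (loads, solution)."""
    return unit_section_loads(coarse_model)


@pytest.fixture(scope="session")
def unit_moment(coarse_state):
    loads, _ = coarse_state
    return abs(loads.Mz)


@pytest.fixture(scope="session")
def cantilever():
    """Plate-only cantilever solved under a transverse tip displacement.

    Geometry matches the bridging plate (24.25 x 4.25 x 1 mm, PEEK-like
    constants); the tip face is driven in y only so the section can
    rotate freely — the Euler-Bernoulli 3EI*delta/L^3 configuration.
    """
    L, W, t, E, nu, delta = 24.25, 4.25, 1.0, 3600.0, 0.38, 0.1
    mesh = mesh_box([L, t, W], 0.7, origin=(0.0, 4.5, -W / 2))
    mat = assign_materials(mesh, {"plate": (E, nu)})
    K = assemble(mesh, mat)
    x = mesh.nodes
    root = np.nonzero(np.abs(x[:, 0]) < 1e-9)[0]
    tip = np.nonzero(np.abs(x[:, 0] - L) < 1e-9)[0]
    bcs = BoundaryConditions(
        pinned=root,
        prescribed=tip,
        prescribed_values=np.tile([0.0, delta, 0.0], (len(tip), 1)),
        prescribed_mask=np.tile([False, True, False], (len(tip), 1)),
    )
    sol = solve(K, bcs, mesh.nodes)
    return dict(
        mesh=mesh, materials=mat, solution=sol, K=K, root=root, tip=tip,
        L=L, W=W, t=t, E=E, nu=nu, delta=delta,
        I=W * t**3 / 12.0,
    )
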