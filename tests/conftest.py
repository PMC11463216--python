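"""Shared fixtures: the hexacone seed and small synthetic mesh patches."""

from __future__ import annotations

import numpy as np
import pytest

from coralclone.mesh import ColonyMesh
from coralclone.simulator import make_hexacone_seed


@pytest.fixture
def seed_state():
    return make_hexacone_seed(10.0)


@pytest.fixture
def seed_mesh(seed_state):
    return seed_state.mesh


def make_hex_patch(rings: int = 2, a: float = 1.0, z: float = 0.0) -> ColonyMesh:
    """Flat triangulated sheet on a regular triangular lattice.

    A rhombus of (rings+1) x (rings+1) lattice points with unit spacing
    ``a``; every interior vertex has degree 6 and normal +z.  Faces are
    wound counter-clockwise seen from above.
    """
    mesh = ColonyMesh()
    n = rings + 1
    vid = {}
    for i in range(n):
        for j in range(n):
            vid[(i, j)] = mesh.add_vertex(
                (a * (i + 0.5 * j), a * j * np.sqrt(3) / 2.0, z)
            )
    for i in range(rings):
        for j in range(rings):
            mesh.add_face(vid[(i, j)], vid[(i + 1, j)], vid[(i, j + 1)])
            mesh.add_face(vid[(i + 1, j)], vid[(i + 1, j + 1)], vid[(i, j + 1)])
    return mesh


@pytest.fixture
def hex_patch():
    return make_hex_patch(rings=4, a=1.0)


def make_nonmanifold_collapse_fixture() -> tuple[ColonyMesh, tuple[int, int]]:
    """5-vertex planar fixture where collapsing edge (u, v) would create a
    non-manifold fin: u and v share the neighbour c that is not opposite
    the edge, violating the link condition."""
    mesh = ColonyMesh()
    u = mesh.add_vertex((0.0, 0.0, 0.0))
    v = mesh.add_vertex((1.0, 0.0, 0.0))
    a = mesh.add_vertex((0.5, 1.0, 0.0))
    b = mesh.add_vertex((0.5, -1.0, 0.0))
    c = mesh.add_vertex((0.5, 2.0, 0.0))
    mesh.add_face(u, v, a)
    mesh.add_face(u, b, v)
    mesh.add_face(v, c, a)
    mesh.add_face(u, a, c)
    return mesh, (u, v)


def make_ladder_mesh(n_rungs: int = 13, dz: float = 5.0, width: float = 5.0) -> ColonyMesh:
    """Vertical two-column strip (a synthetic 'trunk' stand-in): vertices at
    (0, 0, k*dz) and (width, 0, k*dz), triangulated between columns."""
    mesh = ColonyMesh()
    left = [mesh.add_vertex((0.0, 0.0, k * dz)) for k in range(n_rungs)]
    right = [mesh.add_vertex((width, 0.0, k * dz)) for k in range(n_rungs)]
    for k in range(n_rungs - 1):
        mesh.add_face(left[k], right[k], left[k + 1])
        mesh.add_face(right[k], right[k + 1], left[k + 1])
    return mesh


def make_cylinder_mesh(
    radius: float, height: float, n_theta: int = 48, n_z: int = 30
) -> ColonyMesh:
    """Open triangulated cylinder around the z-axis (synthetic branch)."""
    mesh = ColonyMesh()
    rows = []
    for k in range(n_z + 1):
        z = height * k / n_z
        rows.append(
            [
                mesh.add_vertex(
                    (
                        radius * np.cos(2 * np.pi * i / n_theta),
                        radius * np.sin(2 * np.pi * i / n_theta),
                        z,
                    )
                )
                for i in range(n_theta)
            ]
        )
    for k in range(n_z):
        for i in range(n_theta):
            j = (i + 1) % n_theta
            mesh.add_face(rows[k][i], rows[k][j], rows[k + 1][i])
            mesh.add_face(rows[k][j], rows[k + 1][j], rows[k + 1][i])
    return mesh
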