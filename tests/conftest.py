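"""Shared fixtures: one zoned reference leg per session plus helpers.

Meshes are built at a moderate resolution (16 circumferential segments)
so the whole suite stays fast; resolution-sensitivity is tested where it
matters, not everywhere.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from itmap.leg_model import build_reference_leg, project_views, segment_zones
from itmap.synthetic import paper_like_config


@pytest.fixture(scope="session")
def reference():
    return segment_zones(build_reference_leg(resolution=16))


@pytest.fixture(scope="session")
def template(reference):
    return project_views(reference)


@pytest.fixture(scope="session")
def sim_config():
    return paper_like_config(seed=1)


def make_grid_mesh(nx: int, ny: int, width: float, height: float):
    """Planar rectangular patch triangulated on a regular grid."""
    xs = np.linspace(0.0, width, nx)
    ys = np.linspace(0.0, height, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    vertices = np.stack([X.ravel(), Y.ravel(), np.zeros(nx * ny)], axis=1)
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            c = (i + 1) * ny + j + 1
            d = i * ny + j + 1
            faces.extend([(a, b, c), (a, c, d)])
    return SimpleNamespace(vertices=vertices, faces=np.asarray(faces))


def make_cylinder_mesh(n_around: int, n_axial: int, radius: float, height: float):
    """Open cylinder around +z; supports the developable-surface oracle."""
    theta = np.arange(n_around) * 2.0 * np.pi / n_around
    rings = [
        np.stack(
            [radius * np.cos(theta), radius * np.sin(theta), np.full(n_around, z)],
            axis=1,
        )
        for z in np.linspace(0.0, height, n_axial + 1)
    ]
    vertices = np.vstack(rings)
    faces = []
    for k in range(n_axial):
        b0, b1 = k * n_around, (k + 1) * n_around
        for j in range(n_around):
            jn = (j + 1) % n_around
            faces.extend([(b0 + j, b0 + jn, b1 + j), (b0 + jn, b1 + jn, b1 + j)])
    return SimpleNamespace(vertices=vertices, faces=np.asarray(faces))


def vertex_anchor(mesh, vertex_index: int):
    """(face, barycentric) anchor at an existing mesh vertex."""
    face = int(np.argwhere((mesh.faces == vertex_index).any(axis=1))[0][0])
    bary = np.zeros(3)
    bary[list(mesh.faces[face]).index(vertex_index)] = 1.0
    return face, bary


def sample_surface_points(mesh, n: int, rng):
    """Area-weighted uniform anchors on a mesh."""
    tri = mesh.vertices[mesh.faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    p = areas / areas.sum()
    faces = rng.choice(len(p), size=n, p=p)
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    bary = np.stack([1 - r1, r1 * (1 - r2), r1 * r2], axis=1)
    return faces, bary
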