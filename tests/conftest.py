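"""Shared fixtures: small analytic meshes and cached synthetic specimens."""

from __future__ import annotations

import numpy as np
import pytest

from morphoheart.mesh_core import Mesh
from morphoheart.synthetic_embryo import SynthParams, generate_specimen


def make_tetrahedron() -> Mesh:
    v = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
                  [0.0, 0.0, 1.0]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return Mesh(v, f, name="tetra")


def make_torus(R: float = 3.0, r: float = 1.0, n: int = 24, m: int = 16) -> Mesh:
    uu = np.arange(n) * 2 * np.pi / n
    vv = np.arange(m) * 2 * np.pi / m
    verts = np.array([[(R + r * np.cos(v)) * np.cos(u),
                       (R + r * np.cos(v)) * np.sin(u),
                       r * np.sin(v)] for u in uu for v in vv])
    faces = []
    for i in range(n):
        for j in range(m):
            a = i * m + j
            b = ((i + 1) % n) * m + j
            c = ((i + 1) % n) * m + (j + 1) % m
            d = i * m + (j + 1) % m
            faces += [(a, b, c), (a, c, d)]
    return Mesh(verts, np.asarray(faces), name="torus")


def make_strip(length: float = 10.0, width: float = 1.0,
               nx: int = 21, ny: int = 3) -> Mesh:
    """Planar rectangular strip in the xy plane (open, one boundary loop)."""
    xs = np.linspace(0.0, length, nx)
    ys = np.linspace(0.0, width, ny)
    verts = np.array([[x, y, 0.0] for x in xs for y in ys])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            c = (i + 1) * ny + j + 1
            d = i * ny + j + 1
            faces += [(a, b, c), (a, c, d)]
    return Mesh(verts, np.asarray(faces), name="strip")


def subdivide(mesh: Mesh) -> Mesh:
    """Uniform 1-to-4 triangle subdivision (midpoint scheme)."""
    verts = list(map(tuple, mesh.vertices))
    index = {v: i for i, v in enumerate(verts)}

    def midpoint(a, b):
        p = tuple((mesh.vertices[a] + mesh.vertices[b]) / 2.0)
        if p not in index:
            index[p] = len(verts)
            verts.append(p)
        return index[p]

    faces = []
    for a, b, c in mesh.faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        faces += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
    return Mesh(np.asarray(verts), np.asarray(faces), name=mesh.name + "-sub")


_SPECIMEN_CACHE: dict = {}


def specimen(t: float, noise: float = 0.0, seed: int = 0, **kw):
    """Cached synthetic specimen (generation is deterministic)."""
    key = (t, noise, seed, tuple(sorted(kw.items())))
    if key not in _SPECIMEN_CACHE:
        _SPECIMEN_CACHE[key] = generate_specimen(
            SynthParams(t=t, noise_sigma=noise, seed=seed, **kw))
    return _SPECIMEN_CACHE[key]


@pytest.fixture(scope="session")
def tetra() -> Mesh:
    return make_tetrahedron()


@pytest.fixture(scope="session")
def torus() -> Mesh:
    return make_torus()


@pytest.fixture(scope="session")
def strip() -> Mesh:
    return make_strip()
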