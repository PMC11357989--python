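"""Triangle-mesh data model, I/O, topology checks, registration and geodesics.

This is the substrate the whole pipeline rests on: indexed triangle surfaces
of segmented embryonic tissues, with coordinates in micrometres throughout.
The frame convention used repo-wide is

    x : left (-) to right (+)
    y : ventral (-) to dorsal (+)
    z : caudal (0) to cranial (+)   (the anterior-posterior axis)

Geodesic distances are shortest paths along mesh edges with Euclidean edge
weights (graph geodesics), which for dense tissue meshes is indistinguishable
from exact polyhedral geodesics at the scales measured here.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .errors import (
    AmbiguityError,
    DegenerateInputError,
    GeometryError,
    MeshFormatError,
    NoPathError,
    TopologyError,
)

__all__ = [
    "Mesh",
    "LandmarkSet",
    "RigidTransform",
    "read_mesh",
    "write_mesh",
    "euler_genus",
    "rigid_register",
    "procrustes",
    "geodesic_distance",
    "outline_distance",
    "boundary_subarc",
]

_FORMATS = ("ply", "off", "obj")


@dataclass
class Mesh:
    """Indexed triangle surface.

    Parameters
    ----------
    vertices : (V, 3) float array, micrometres.
    faces : (F, 3) int array of vertex indices, consistently wound.
    name : free-text identifier.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (V, 3) array")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise MeshFormatError("faces must be an (F, 3) array")
        if self.faces.size == 0:
            self.faces = self.faces.reshape(0, 3)

    # -- basic counts ------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self, name: str | None = None) -> "Mesh":
        return Mesh(self.vertices.copy(), self.faces.copy(),
                    self.name if name is None else name)

    # -- topology ----------------------------------------------------------
    def edges(self) -> np.ndarray:
        """All directed half-edges, one row per face edge, shape (3F, 2)."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]], axis=0)

    def edges_unique(self, return_counts: bool = False):
        und = np.sort(self.edges(), axis=1)
        uniq, counts = np.unique(und, axis=0, return_counts=True)
        if return_counts:
            return uniq, counts
        return uniq

    def validate(self) -> None:
        """Raise if face indices are out of range, faces repeat, or the
        surface is non-orientable / non-manifold along an edge."""
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise MeshFormatError("face references a vertex index out of range")
        canon = np.sort(self.faces, axis=1)
        if len(np.unique(canon, axis=0)) != self.n_faces:
            raise MeshFormatError("duplicate faces present")
        uniq, counts = self.edges_unique(return_counts=True)
        if counts.max(initial=0) > 2:
            raise TopologyError("non-manifold edge shared by more than two faces")
        # orientability: each undirected edge used twice must appear once in
        # each direction among the directed half-edges
        he = self.edges()
        directed, dcounts = np.unique(he, axis=0, return_counts=True)
        if dcounts.max(initial=0) > 1:
            raise TopologyError("surface is not consistently oriented")

    def is_closed(self) -> bool:
        _, counts = self.edges_unique(return_counts=True)
        return bool(counts.size) and bool((counts == 2).all())

    def is_connected(self) -> bool:
        return self.connected_component_count() == 1

    def connected_component_count(self) -> int:
        uniq = self.edges_unique()
        g = coo_matrix(
            (np.ones(len(uniq)), (uniq[:, 0], uniq[:, 1])),
            shape=(self.n_vertices, self.n_vertices),
        )
        n, _ = connected_components(g, directed=False)
        return int(n)

    def boundary_edges(self) -> np.ndarray:
        uniq, counts = self.edges_unique(return_counts=True)
        return uniq[counts == 1]

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex loops of the boundary (closed mesh: empty list)."""
        be = self.boundary_edges()
        if len(be) == 0:
            return []
        adj: dict[int, list[int]] = {}
        for a, b in be:
            adj.setdefault(int(a), []).append(int(b))
            adj.setdefault(int(b), []).append(int(a))
        unused = {tuple(sorted((int(a), int(b)))) for a, b in be}
        loops = []
        while unused:
            a, b = next(iter(unused))
            loop = [a, b]
            unused.discard((min(a, b), max(a, b)))
            while True:
                cur, prev = loop[-1], loop[-2]
                nxts = [v for v in adj[cur]
                        if v != prev and tuple(sorted((cur, v))) in unused]
                if not nxts:
                    break
                nxt = nxts[0]
                unused.discard(tuple(sorted((cur, nxt))))
                if nxt == loop[0]:
                    break
                loop.append(nxt)
            loops.append(np.asarray(loop, dtype=np.int64))
        return loops

    # -- geometry ----------------------------------------------------------
    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def mean_edge_length(self) -> float:
        uniq = self.edges_unique()
        d = np.linalg.norm(self.vertices[uniq[:, 0]] - self.vertices[uniq[:, 1]], axis=1)
        return float(d.mean())

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (via trimesh)."""
        return np.asarray(self.to_trimesh().vertex_normals, dtype=np.float64)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def transformed(self, transform: "RigidTransform") -> "Mesh":
        return Mesh(transform.apply(self.vertices), self.faces.copy(), self.name)


@dataclass
class RigidTransform:
    """Similarity transform  p -> scale * R p + t  with det(R) = +1."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if self.scale <= 0:
            raise DegenerateInputError("scale must be positive")
        if np.linalg.det(self.rotation) < 0:
            raise DegenerateInputError("rotation must not contain a reflection")

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        return self.scale * p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation / self.scale,
                              1.0 / self.scale)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3), 1.0)


# -- landmarks --------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Named landmarks on (or near) a mesh.

    Each entry is one of
      - a vertex index                       {"vertex": i}
      - a free 3D point                      {"point": [x, y, z]}
      - a vertex-index region                {"vertices": [...]}
      - a free unit direction vector         {"vector": [x, y, z]}
    ``frame`` records the axis convention tag (default repo standard).
    """

    entries: dict = field(default_factory=dict)
    frame: str = "x:left-right y:ventral-dorsal z:caudal-cranial"

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise AmbiguityError("landmark names must be unique")

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self) -> list[str]:
        return list(self.entries)

    def vertex(self, name: str) -> int:
        from .errors import LandmarkError

        e = self.entries.get(name)
        if e is None or "vertex" not in e:
            raise LandmarkError(f"landmark {name!r} missing or not a vertex landmark")
        return int(e["vertex"])

    def point(self, name: str, mesh: Mesh | None = None) -> np.ndarray:
        from .errors import LandmarkError

        e = self.entries.get(name)
        if e is None:
            raise LandmarkError(f"landmark {name!r} missing")
        if "point" in e:
            return np.asarray(e["point"], dtype=np.float64)
        if "vertex" in e:
            if mesh is None:
                raise LandmarkError(f"landmark {name!r} is a vertex index; mesh required")
            idx = int(e["vertex"])
            if not 0 <= idx < mesh.n_vertices:
                raise LandmarkError(
                    f"landmark {name!r} references vertex {idx}, outside the mesh")
            return mesh.vertices[idx]
        raise LandmarkError(f"landmark {name!r} has no point representation")

    def region(self, name: str) -> np.ndarray:
        from .errors import LandmarkError

        e = self.entries.get(name)
        if e is None or "vertices" not in e:
            raise LandmarkError(f"landmark {name!r} missing or not a region")
        return np.asarray(e["vertices"], dtype=np.int64)

    def vector(self, name: str) -> np.ndarray:
        from .errors import LandmarkError

        e = self.entries.get(name)
        if e is None or "vector" not in e:
            raise LandmarkError(f"landmark {name!r} missing or not a vector")
        return np.asarray(e["vector"], dtype=np.float64)

    def validate_for(self, mesh: Mesh) -> None:
        for name, e in self.entries.items():
            idx = []
            if "vertex" in e:
                idx = [int(e["vertex"])]
            elif "vertices" in e:
                idx = [int(i) for i in e["vertices"]]
            for i in idx:
                if not 0 <= i < mesh.n_vertices:
                    raise MeshFormatError(
                        f"landmark {name!r} references invalid vertex {i}")

    # JSON round trip ------------------------------------------------------
    def to_json(self, path: str | os.PathLike) -> None:
        def clean(e):
            out = {}
            for k, v in e.items():
                out[k] = v.tolist() if isinstance(v, np.ndarray) else (
                    int(v) if k == "vertex" else v)
            return out

        payload = {"frame": self.frame,
                   "landmarks": {k: clean(v) for k, v in self.entries.items()}}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @staticmethod
    def from_json(path: str | os.PathLike) -> "LandmarkSet":
        with open(path) as fh:
            payload = json.load(fh)
        if "landmarks" in payload:
            return LandmarkSet(entries=payload["landmarks"],
                               frame=payload.get("frame", LandmarkSet().frame))
        return LandmarkSet(entries=payload)


# -- I/O --------------------------------------------------------------------

def _infer_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is None:
        fmt = os.path.splitext(str(path))[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def _check_triangular_ascii(path: str, fmt: str) -> None:
    """Scan an ASCII mesh file and report the first non-triangular face."""
    with open(path, "rb") as fh:
        head = fh.read(64)
    try:
        text_probe = head.decode("ascii")
    except UnicodeDecodeError:
        return  # binary PLY: handled by the trimesh loader
    if fmt == "ply" and "format ascii" not in open(path, errors="ignore").read(256):
        return
    lines = open(path, errors="ignore").read().splitlines()
    face_lines: list[tuple[int, int]] = []  # (face index, vertex count)
    if fmt == "obj":
        n = 0
        for ln in lines:
            if ln.startswith("f "):
                face_lines.append((n, len(ln.split()) - 1))
                n += 1
    elif fmt == "off":
        body = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
        if not body or not body[0].startswith("OFF"):
            return
        counts = body[0][3:].split() or body[1].split()
        start = 1 if body[0][3:].split() else 2
        try:
            nv, nf = int(counts[0]), int(counts[1])
        except (ValueError, IndexError):
            return
        for i, ln in enumerate(body[start + nv:start + nv + nf]):
            toks = ln.split()
            if toks:
                face_lines.append((i, int(float(toks[0]))))
    elif fmt == "ply":
        nv = nf = None
        end = None
        for i, ln in enumerate(lines):
            if ln.startswith("element vertex"):
                nv = int(ln.split()[-1])
            elif ln.startswith("element face"):
                nf = int(ln.split()[-1])
            elif ln.strip() == "end_header":
                end = i
                break
        if None in (nv, nf, end):
            return
        for i, ln in enumerate(lines[end + 1 + nv:end + 1 + nv + nf]):
            toks = ln.split()
            if toks:
                face_lines.append((i, int(float(toks[0]))))
    for idx, cnt in face_lines:
        if cnt != 3:
            raise MeshFormatError(
                f"face {idx} has {cnt} vertices; only triangle meshes are supported")


def read_mesh(path: str | os.PathLike, fmt: str | None = None) -> Mesh:
    """Read a PLY (ascii or binary), OFF or OBJ triangle mesh.

    Coordinates and units are passed through unchanged.  Non-triangular
    faces raise :class:`MeshFormatError` naming the offending face.
    """
    fmt = _infer_format(path, fmt)
    if not os.path.exists(path):
        raise IOError(f"mesh file not found: {path}")
    _check_triangular_ascii(str(path), fmt)
    try:
        loaded = trimesh.load(str(path), file_type=fmt, process=False,
                              maintain_order=True)
    except MeshFormatError:
        raise
    except Exception as exc:  # parser failures are I/O-level errors to callers
        raise IOError(f"could not read {path} as {fmt}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.vertices) == 0:
        raise IOError(f"could not read {path} as {fmt}: no mesh content")
    name = os.path.splitext(os.path.basename(str(path)))[0]
    mesh = Mesh(np.asarray(loaded.vertices, dtype=np.float64),
                np.asarray(loaded.faces, dtype=np.int64), name=name)
    if mesh.faces.size and mesh.faces.max() >= mesh.n_vertices:
        raise MeshFormatError(f"{path}: face index out of range")
    return mesh


def write_mesh(mesh: Mesh, path: str | os.PathLike, fmt: str | None = None,
               binary: bool = False) -> None:
    """Write a mesh as PLY (ascii by default, binary on request), OFF or OBJ.

    Coordinates are written at full float64 precision so that write/read
    round trips are exact to well below 1e-6 um.
    """
    fmt = _infer_format(path, fmt)
    v, f = mesh.vertices, mesh.faces
    buf = io.StringIO()
    if fmt == "ply" and binary:
        header = (
            "ply\nformat binary_little_endian 1.0\n"
            f"element vertex {len(v)}\n"
            "property double x\nproperty double y\nproperty double z\n"
            f"element face {len(f)}\n"
            "property list uchar int vertex_indices\nend_header\n"
        )
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(v.astype("<f8").tobytes())
            rec = np.empty(len(f), dtype=[("n", "u1"), ("idx", "<i4", (3,))])
            rec["n"] = 3
            rec["idx"] = f
            fh.write(rec.tobytes())
        return
    if fmt == "ply":
        buf.write("ply\nformat ascii 1.0\n")
        buf.write(f"element vertex {len(v)}\n")
        buf.write("property double x\nproperty double y\nproperty double z\n")
        buf.write(f"element face {len(f)}\n")
        buf.write("property list uchar int vertex_indices\nend_header\n")
        for p in v:
            buf.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        for t in f:
            buf.write(f"3 {t[0]} {t[1]} {t[2]}\n")
    elif fmt == "off":
        buf.write("OFF\n")
        buf.write(f"{len(v)} {len(f)} 0\n")
        for p in v:
            buf.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        for t in f:
            buf.write(f"3 {t[0]} {t[1]} {t[2]}\n")
    elif fmt == "obj":
        for p in v:
            buf.write(f"v {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        for t in f:
            buf.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
    tmp = f"{path}.tmp-{os.getpid()}"
    with open(tmp, "w") as fh:
        fh.write(buf.getvalue())
    os.replace(tmp, path)


# -- topology ---------------------------------------------------------------

def euler_genus(mesh: Mesh) -> int:
    """Genus of a closed, connected triangle surface via the Euler count
    g = (2 - V + E - F) / 2."""
    if not mesh.is_closed():
        raise TopologyError("mesh is open (has boundary edges); genus undefined")
    if not mesh.is_connected():
        raise TopologyError("mesh has multiple connected components; genus undefined")
    V = mesh.n_vertices
    E = len(mesh.edges_unique())
    F = mesh.n_faces
    chi = V - E + F
    g2 = 2 - chi
    if g2 < 0 or g2 % 2:
        raise TopologyError(f"Euler characteristic {chi} is not that of a closed surface")
    return g2 // 2


# -- registration -----------------------------------------------------------

def procrustes(source_points: np.ndarray, target_points: np.ndarray,
               allow_scale: bool = False) -> tuple[RigidTransform, float]:
    """Least-squares rigid (optionally similarity) alignment of paired points.

    Closed-form orthogonal-Procrustes solution via SVD; the reflection case
    is excluded by sign-correcting the smallest singular direction.  Returns
    the transform mapping source onto target and the residual RMS.
    """
    src = np.asarray(source_points, dtype=np.float64)
    dst = np.asarray(target_points, dtype=np.float64)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise DegenerateInputError("paired point arrays must both be (N, 3)")
    n = len(src)
    if n < 3:
        raise DegenerateInputError(f"need at least 3 point pairs, got {n}")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    sc, dc = src - mu_s, dst - mu_d
    # collinearity check: rank of the centred source configuration
    if np.linalg.matrix_rank(sc, tol=1e-9 * max(1.0, np.abs(sc).max())) < 2:
        raise DegenerateInputError("point pairs are collinear; rotation unresolved")
    H = sc.T @ dc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if allow_scale:
        var_s = (sc ** 2).sum()
        scale = float((S * np.diag(D)).sum() / var_s) if var_s > 0 else 1.0
    else:
        scale = 1.0
    t = mu_d - scale * R @ mu_s
    tf = RigidTransform(R, t, scale)
    rms = float(np.sqrt(((tf.apply(src) - dst) ** 2).sum(axis=1).mean()))
    return tf, rms


def rigid_register(source: Mesh, target: Mesh,
                   pairs: Sequence[tuple[int, np.ndarray]],
                   allow_scale: bool = False) -> tuple[RigidTransform, float]:
    """Register ``source`` onto ``target`` from >=3 (source vertex, target point)
    pairs; see :func:`procrustes` for the solver and return convention."""
    if len(pairs) < 3:
        raise DegenerateInputError(f"need at least 3 pairs, got {len(pairs)}")
    src = np.array([source.vertices[int(i)] for i, _ in pairs])
    dst = np.array([np.asarray(p, dtype=np.float64) for _, p in pairs])
    return procrustes(src, dst, allow_scale=allow_scale)


# -- geodesics --------------------------------------------------------------

def _edge_graph(mesh: Mesh):
    uniq = mesh.edges_unique()
    w = np.linalg.norm(mesh.vertices[uniq[:, 0]] - mesh.vertices[uniq[:, 1]], axis=1)
    n = mesh.n_vertices
    g = coo_matrix((np.concatenate([w, w]),
                    (np.concatenate([uniq[:, 0], uniq[:, 1]]),
                     np.concatenate([uniq[:, 1], uniq[:, 0]]))), shape=(n, n))
    return g.tocsr()


def geodesic_distance(mesh: Mesh, start: int, end: int) -> float:
    """Length (um) of the shortest path along mesh edges between two vertices."""
    n = mesh.n_vertices
    if not (0 <= start < n and 0 <= end < n):
        raise NoPathError(f"vertex index out of range: {start}, {end}")
    if start == end:
        return 0.0
    dist = dijkstra(_edge_graph(mesh), directed=False, indices=start)
    d = float(dist[end])
    if not np.isfinite(d):
        raise NoPathError(f"vertices {start} and {end} are not connected")
    return d


# -- boundary-outline distances ---------------------------------------------

def _project_to_boundary(mesh: Mesh, loops: list[np.ndarray],
                         point: np.ndarray) -> tuple[int, int]:
    """(loop index, position within loop) of the boundary vertex closest to point."""
    best = (np.inf, -1, -1)
    p = np.asarray(point, dtype=np.float64)
    for li, loop in enumerate(loops):
        d = np.linalg.norm(mesh.vertices[loop] - p, axis=1)
        j = int(np.argmin(d))
        if d[j] < best[0]:
            best = (float(d[j]), li, j)
    return best[1], best[2]


def _loop_arcs(mesh: Mesh, loop: np.ndarray, i: int, j: int):
    """Both boundary arcs (as ordered vertex index arrays) from position i to j."""
    n = len(loop)
    if i == j:
        return np.asarray([loop[i]]), loop[np.arange(i, i + n + 1) % n]
    fwd = loop[np.arange(i, i + ((j - i) % n) + 1) % n]
    bwd = loop[np.arange(j, j + ((i - j) % n) + 1) % n][::-1]
    return fwd, bwd


def _arc_length(mesh: Mesh, arc: np.ndarray) -> float:
    if len(arc) < 2:
        return 0.0
    pts = mesh.vertices[arc]
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def outline_distance(midsurface: Mesh, lm_a: np.ndarray, lm_b: np.ndarray) -> float:
    """Distance along the boundary outline of an open midsurface.

    Each landmark is projected to its closest boundary vertex and the
    accumulated edge length of the shorter of the two boundary arcs between
    the projections is returned.
    """
    loops = midsurface.boundary_loops()
    if not loops:
        raise GeometryError("mesh is closed; outline distances require a boundary")
    la, ia = _project_to_boundary(midsurface, loops, lm_a)
    lb, ib = _project_to_boundary(midsurface, loops, lm_b)
    if la != lb:
        raise AmbiguityError("landmarks project to different boundary loops")
    if ia == ib:
        return 0.0
    fwd, bwd = _loop_arcs(midsurface, loops[la], ia, ib)
    return min(_arc_length(midsurface, fwd), _arc_length(midsurface, bwd))


def boundary_subarc(midsurface: Mesh, lm_a: np.ndarray, lm_b: np.ndarray) -> np.ndarray:
    """Ordered vertex indices of the *shorter* boundary arc between the
    boundary projections of two landmarks (used to delimit the dorsal lips)."""
    loops = midsurface.boundary_loops()
    if not loops:
        raise GeometryError("mesh is closed; boundary sub-arcs require a boundary")
    la, ia = _project_to_boundary(midsurface, loops, lm_a)
    lb, ib = _project_to_boundary(midsurface, loops, lm_b)
    if la != lb:
        raise AmbiguityError("landmarks project to different boundary loops")
    fwd, bwd = _loop_arcs(midsurface, loops[la], ia, ib)
    return fwd if _arc_length(midsurface, fwd) <= _arc_length(midsurface, bwd) else bwd
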