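"""Landmark-driven vertex-to-point maps between topologically equivalent meshes.

A sparse set of corresponding landmarks drives a thin-plate-spline (TPS)
warp of the reference mesh; each warped vertex is then projected to its
closest point on the target surface.  The TPS interpolates the landmark
pairs exactly and reproduces affine motions, so rigidly moved copies map
exactly.  Bijectivity is not guaranteed by this construction and is instead
diagnosed a posteriori (the duplicate-target-face rate on the map).

``cut_to_genus0`` opens torus-topology meshes (the dorsally closed heart
tube, the splanchnic mesoderm) along a prescribed non-separating cycle and
closes the two emerging holes with centroid fans, yielding sphere topology
so that surface maps across a mixed-topology sequence become possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator

from ._spatial import SurfaceQuery
from .errors import (
    ConsistencyError,
    CutError,
    DegenerateInputError,
    TopologyError,
)
from .mesh_core import LandmarkSet, Mesh, euler_genus, procrustes

__all__ = ["CorrespondenceMap", "SurfaceMapper", "landmark_map",
           "landmark_pairs_from_sets", "propagate_connectivity", "cut_to_genus0"]


@dataclass
class CorrespondenceMap:
    """For each reference vertex, a corresponding point on the target surface."""

    reference: str
    target: str
    points: np.ndarray                    # (V_ref, 3), on the target surface
    face_index: np.ndarray | None = None  # containing target face per point
    barycentric: np.ndarray | None = None
    landmark_rms: float = 0.0
    duplicate_face_rate: float = 0.0      # a-posteriori bijectivity diagnostic

    def __len__(self) -> int:
        return len(self.points)


def _topology_signature(mesh: Mesh):
    if mesh.is_closed():
        return ("closed", euler_genus(mesh))
    return ("open", len(mesh.boundary_loops()))


class SurfaceMapper:
    """TPS warp fitted on landmark pairs + closest-point projection onto the
    target; reusable for arbitrary points lying on the reference surface."""

    def __init__(self, reference: Mesh, target: Mesh,
                 ref_points: np.ndarray, tgt_points: np.ndarray):
        ref_points = np.asarray(ref_points, dtype=np.float64)
        tgt_points = np.asarray(tgt_points, dtype=np.float64)
        if ref_points.shape != tgt_points.shape or ref_points.ndim != 2:
            raise ConsistencyError("landmark point arrays must match in shape")
        if len(ref_points) < 4:
            raise DegenerateInputError(
                f"need at least 4 landmark pairs, got {len(ref_points)}")
        sig_r, sig_t = _topology_signature(reference), _topology_signature(target)
        if sig_r != sig_t:
            raise TopologyError(
                f"topology mismatch: reference {sig_r} vs target {sig_t}")
        centred = ref_points - ref_points.mean(axis=0)
        scale = max(1.0, np.abs(centred).max())
        if np.linalg.matrix_rank(centred, tol=1e-9 * scale) < 3:
            raise DegenerateInputError("landmarks are coplanar; TPS warp degenerate")
        self.reference = reference
        self.target = target
        self._warp = RBFInterpolator(ref_points, tgt_points,
                                     kernel="thin_plate_spline", degree=1)
        self._query = SurfaceQuery(target.vertices, target.faces)
        self._ref_points = ref_points
        self._tgt_points = tgt_points

    def map_points(self, points: np.ndarray):
        """Warp + project arbitrary points; returns (points, face indices)."""
        warped = self._warp(np.atleast_2d(np.asarray(points, dtype=np.float64)))
        proj, _, fidx = self._query.closest(warped)
        return proj, fidx

    def build_map(self) -> CorrespondenceMap:
        proj, fidx = self.map_points(self.reference.vertices)
        mapped_lm, _ = self.map_points(self._ref_points)
        rms = float(np.sqrt(((mapped_lm - self._tgt_points) ** 2)
                            .sum(axis=1).mean()))
        bary = _barycentric(self.target, proj, fidx)
        dup = 1.0 - len(np.unique(fidx)) / max(1, len(fidx))
        return CorrespondenceMap(reference=self.reference.name,
                                 target=self.target.name,
                                 points=proj, face_index=fidx,
                                 barycentric=bary, landmark_rms=rms,
                                 duplicate_face_rate=dup)


def _barycentric(mesh: Mesh, points: np.ndarray, face_index: np.ndarray) -> np.ndarray:
    tri = mesh.vertices[mesh.faces[face_index]]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    v0, v1, v2 = b - a, c - a, points - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) > 1e-300, denom, 1.0)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    return np.clip(np.column_stack([1.0 - v - w, v, w]), 0.0, 1.0)


def landmark_pairs_from_sets(ref_mesh: Mesh, tgt_mesh: Mesh,
                             ref_lms: LandmarkSet, tgt_lms: LandmarkSet,
                             names: list[str] | None = None):
    """Resolve shared point-valued landmark names into paired coordinates."""
    if names is None:
        names = [n for n in ref_lms.names()
                 if n in tgt_lms
                 and ("vertex" in ref_lms.entries[n] or "point" in ref_lms.entries[n])
                 and ("vertex" in tgt_lms.entries[n] or "point" in tgt_lms.entries[n])]
    ref_pts = np.array([ref_lms.point(n, ref_mesh) for n in names])
    tgt_pts = np.array([tgt_lms.point(n, tgt_mesh) for n in names])
    # aliased landmark names can point at the same location (e.g. a border
    # endpoint that is also a lip endpoint); duplicates make the TPS singular
    if len(ref_pts):
        _, keep = np.unique(np.round(ref_pts, 9), axis=0, return_index=True)
        keep = np.sort(keep)
        ref_pts, tgt_pts = ref_pts[keep], tgt_pts[keep]
        names = [names[i] for i in keep]
    return ref_pts, tgt_pts, names


def landmark_map(reference: Mesh, target: Mesh,
                 ref_points: np.ndarray, tgt_points: np.ndarray) -> CorrespondenceMap:
    """Map every reference vertex to a point on the target surface from >=4
    non-coplanar landmark pairs (TPS warp + closest-point projection)."""
    return SurfaceMapper(reference, target, ref_points, tgt_points).build_map()


def propagate_connectivity(sequence: list[Mesh],
                           landmark_sets: list[LandmarkSet],
                           stage_values=None):
    """Re-express every mesh of an ordered sequence on the first mesh's
    connectivity by composing consecutive landmark maps, then rigidly align
    all re-expressed shapes to the first.

    Returns a :class:`morphoheart.atlas.KeyframeSequence`.
    """
    from .atlas import KeyframeSequence

    if len(sequence) < 2:
        raise ConsistencyError("sequence must contain at least 2 meshes")
    if len(landmark_sets) != len(sequence):
        raise ConsistencyError("one landmark set per mesh required")

    faces0 = sequence[0].faces
    points = sequence[0].vertices.copy()
    keyframes = [sequence[0].copy()]
    for k in range(len(sequence) - 1):
        ref, tgt = sequence[k], sequence[k + 1]
        sig_r, sig_t = _topology_signature(ref), _topology_signature(tgt)
        if sig_r != sig_t:
            raise TopologyError(
                f"pair ({k} -> {k + 1}): topology mismatch {sig_r} vs {sig_t}")
        try:
            rp, tp, _ = landmark_pairs_from_sets(ref, tgt, landmark_sets[k],
                                                 landmark_sets[k + 1])
            mapper = SurfaceMapper(ref, tgt, rp, tp)
        except (TopologyError, DegenerateInputError, ConsistencyError) as exc:
            raise type(exc)(f"pair ({k} -> {k + 1}): {exc}") from exc
        points, _ = mapper.map_points(points)
        keyframes.append(Mesh(points.copy(), faces0.copy(), name=tgt.name))

    ref_v = keyframes[0].vertices
    for k in range(1, len(keyframes)):
        tf, _ = procrustes(keyframes[k].vertices, ref_v, allow_scale=False)
        keyframes[k] = Mesh(tf.apply(keyframes[k].vertices), faces0.copy(),
                            keyframes[k].name)
    return KeyframeSequence(keyframes=keyframes, stage_values=stage_values,
                            landmark_sets=list(landmark_sets))


# -- genus-1 -> genus-0 cutting ---------------------------------------------

def cut_to_genus0(mesh: Mesh, cut_path) -> tuple[Mesh, bool]:
    """Open a closed genus-1 mesh along a non-separating edge cycle and close
    the two emerging holes with centroid fans.

    Returns ``(mesh, warned)``; a genus-0 input is returned unchanged with
    ``warned=True``.
    """
    g = euler_genus(mesh)
    if g == 0:
        return mesh, True
    if g != 1:
        raise TopologyError(f"cut_to_genus0 expects genus 1, got genus {g}")

    path = [int(v) for v in cut_path]
    if len(path) >= 2 and path[0] == path[-1]:
        path = path[:-1]
    if len(path) < 3 or len(set(path)) != len(path):
        raise CutError("cut path must be a simple cycle of at least 3 vertices")

    directed = {}
    for fi, (a, b, c) in enumerate(mesh.faces):
        directed[(int(a), int(b))] = fi
        directed[(int(b), int(c))] = fi
        directed[(int(c), int(a))] = fi

    m = len(path)
    for k in range(m):
        a, b = path[k], path[(k + 1) % m]
        if (a, b) not in directed or (b, a) not in directed:
            raise CutError(f"cut path hop {a}->{b} is not a mesh edge")

    path_edges = {frozenset((path[k], path[(k + 1) % m])) for k in range(m)}

    faces = mesh.faces.copy()
    vertices = [mesh.vertices]
    n_orig = mesh.n_vertices

    # faces incident to each path vertex
    incident: dict[int, list[int]] = {v: [] for v in path}
    for fi, tri in enumerate(mesh.faces):
        for v in tri:
            if int(v) in incident:
                incident[int(v)].append(fi)

    next_new = n_orig
    dup_of = {}
    for k in range(m):
        v = path[k]
        nxt = path[(k + 1) % m]
        prv = path[(k - 1) % m]
        # seed faces on the duplicated side: those containing the directed
        # half-edges v->nxt and prv->v (consistent orientation puts them on
        # one geometric side of the path)
        seeds = {directed[(v, nxt)], directed[(prv, v)]}
        sector = set(seeds)
        grew = True
        while grew:
            grew = False
            for fi in incident[v]:
                if fi in sector:
                    continue
                tri = mesh.faces[fi]
                others = [int(x) for x in tri if int(x) != v]
                for o in others:
                    if frozenset((v, o)) in path_edges:
                        continue
                    for fj in incident[v]:
                        if fj in sector and fj != fi:
                            tj = set(int(x) for x in mesh.faces[fj])
                            if v in tj and o in tj:
                                sector.add(fi)
                                grew = True
                                break
                    if fi in sector:
                        break
        dup = next_new
        next_new += 1
        dup_of[v] = dup
        for fi in sector:
            faces[fi][faces[fi] == v] = dup
    vertices.append(mesh.vertices[path])  # duplicates share coordinates

    new_vertices = np.concatenate(vertices, axis=0)
    out = Mesh(new_vertices, faces, name=mesh.name + "-cut")

    loops = out.boundary_loops()
    if len(loops) != 2:
        raise CutError(
            f"cut produced {len(loops)} boundary loops (expected 2); "
            "the path is separating or invalid")

    # fan-triangulate both holes from their centroids
    dir_out = set(map(tuple, out.edges()))
    cap_faces = []
    cap_vertices = []
    nv = out.n_vertices
    for loop in loops:
        centroid = out.vertices[loop].mean(axis=0)
        c = nv + len(cap_vertices)
        cap_vertices.append(centroid)
        for i in range(len(loop)):
            a, b = int(loop[i]), int(loop[(i + 1) % len(loop)])
            if (a, b) not in dir_out:
                a, b = b, a
            cap_faces.append((b, a, c))
    closed = Mesh(np.concatenate([out.vertices, np.asarray(cap_vertices)]),
                  np.concatenate([out.faces, np.asarray(cap_faces, dtype=np.int64)]),
                  name=mesh.name + "-cut")
    if closed.connected_component_count() != 1:
        raise CutError("cut path is separating: result is disconnected")
    if euler_genus(closed) != 0:
        raise CutError("cut did not reduce the genus to 0; invalid cut path")
    return closed, False
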