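"""Group-wise mean shapes, per-vertex variability and medoid identification.

Once every specimen of a staging group is expressed as a point set in
vertex-to-point correspondence with a reference mesh and rigidly aligned to
it, the mean shape of the group (MSG) is the per-vertex arithmetic mean.
Local variability is the standard deviation per cluster of corresponding
vertices, taken as the square root of the largest eigenvalue of the 3x3
covariance matrix of the cluster (population convention, divide by n).  The
representative shape of the group (RSG) is the medoid: the member whose
accumulated morphological distance to all others is smallest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConsistencyError, ParameterError
from .mesh_core import Mesh, procrustes

__all__ = ["MeanShapeResult", "align_group", "mean_shape",
           "morph_distance", "medoid", "centroid_size"]


@dataclass
class MeanShapeResult:
    """Mean mesh on the reference connectivity plus per-vertex variability.

    ``per_vertex_sd`` is NaN throughout when fewer than 2 specimens are
    available (variability undefined), mirroring how sparsely populated
    stage groups are treated.
    """

    mean_mesh: Mesh
    per_vertex_sd: np.ndarray
    n_specimens: int
    reference_id: str = ""


def align_group(reference: Mesh, others: list, maps: list) -> list[np.ndarray]:
    """Rigidly register each specimen's corresponding point set onto the
    reference vertices (rotation + translation only, no scaling).

    ``maps[i]`` must be the CorrespondenceMap from the reference onto
    ``others[i]``; its points (one per reference vertex) are returned in the
    reference frame.
    """
    if len(others) != len(maps):
        raise ConsistencyError("one correspondence map per non-reference specimen")
    ref_v = reference.vertices
    aligned = []
    for mesh, cmap in zip(others, maps):
        pts = np.asarray(cmap.points, dtype=np.float64)
        if len(pts) != len(ref_v):
            raise ConsistencyError(
                f"map supplies {len(pts)} points for {len(ref_v)} reference vertices")
        if cmap.target and mesh.name and cmap.target != mesh.name:
            raise ConsistencyError(
                f"map targets {cmap.target!r} but specimen is {mesh.name!r}")
        tf, _ = procrustes(pts, ref_v, allow_scale=False)
        aligned.append(tf.apply(pts))
    return aligned


def mean_shape(point_sets: list, reference: Mesh) -> MeanShapeResult:
    """Per-vertex mean of aligned corresponding point sets, with per-vertex
    variability (sqrt of the largest eigenvalue of the 3x3 population
    covariance of each vertex's corresponding points)."""
    if not point_sets:
        raise ParameterError("need at least one point set")
    stack = np.stack([np.asarray(p, dtype=np.float64) for p in point_sets])
    if stack.shape[1] != reference.n_vertices:
        raise ConsistencyError("point sets must match the reference vertex count")
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    if n < 2:
        sd = np.full(reference.n_vertices, np.nan)
    else:
        centred = stack - mean[None]
        cov = np.einsum("nvi,nvj->vij", centred, centred) / n
        eigvals = np.linalg.eigvalsh(cov)  # ascending
        sd = np.sqrt(np.maximum(eigvals[:, -1], 0.0))
        # identical corresponding points give exactly zero variability, not
        # a rounding-level residual from the mean subtraction
        identical = (np.ptp(stack, axis=0) == 0.0).all(axis=1)
        sd[identical] = 0.0
    return MeanShapeResult(mean_mesh=Mesh(mean, reference.faces.copy(),
                                          name=reference.name + "-mean"),
                           per_vertex_sd=sd, n_specimens=n,
                           reference_id=reference.name)


def centroid_size(points: np.ndarray) -> float:
    """Root-mean-square distance of the points to their centroid."""
    p = np.asarray(points, dtype=np.float64)
    c = p - p.mean(axis=0)
    return float(np.sqrt((c ** 2).sum(axis=1).mean()))


def morph_distance(a: np.ndarray, b: np.ndarray,
                   normalize_scale: bool = False) -> float:
    """Morphological distance D: mean Euclidean distance over corresponding
    vertex pairs.

    With ``normalize_scale`` both sets are centred and uniformly scaled to
    unit centroid size, removing global size differences so that D reflects
    local morphological variation; the result is rescaled by the geometric
    mean of the two original centroid sizes, keeping D symmetric and in um.
    """
    pa = np.asarray(a, dtype=np.float64)
    pb = np.asarray(b, dtype=np.float64)
    if pa.shape != pb.shape:
        raise ConsistencyError(
            f"point counts differ: {pa.shape} vs {pb.shape}")
    if normalize_scale:
        ca, cb = centroid_size(pa), centroid_size(pb)
        if ca <= 0 or cb <= 0:
            raise ConsistencyError("degenerate point set: zero centroid size")
        pa = (pa - pa.mean(axis=0)) / ca
        pb = (pb - pb.mean(axis=0)) / cb
        return float(np.linalg.norm(pa - pb, axis=1).mean()
                     * np.sqrt(ca * cb))
    return float(np.linalg.norm(pa - pb, axis=1).mean())


def medoid(group: list, normalize_scale: bool = True) -> tuple[int, np.ndarray]:
    """Medoid of a group of corresponding point sets.

    q_i = sum over j != i of D(S_i, S_j); returns (argmin q, q).  Ties go to
    the lowest index.
    """
    n = len(group)
    if n < 2:
        raise ParameterError(f"medoid needs at least 2 group members, got {n}")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = morph_distance(group[i], group[j],
                                               normalize_scale=normalize_scale)
    q = D.sum(axis=1)
    return int(np.argmin(q)), q
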