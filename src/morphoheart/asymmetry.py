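"""Left-right asymmetry of the inflow tracts and mirror-fit comparison.

The direction of insertion of each inflow tract (IFT) is the principal axis
of its vertex region, expressed in polar coordinates of the standard embryo
frame: theta in the transverse xy plane (the x axis is flipped when scoring
the right IFT, so a mirror-symmetric pair yields theta_l - theta_r = 0) and
phi as the angle to the cranio-caudal z axis with a -90 degree offset (a
direction lying in the transverse plane scores phi = 0).

The theta zero direction (+y, dorsal) and sign (via atan2 of the x over the
y component) are fixed package conventions; absolute theta values may
differ from other conventions by a constant offset/sign, but the left-right
*differences* that carry the biology are unaffected.

``mirror_fit`` quantifies whole-tissue left-right asymmetry by reflecting
one side of a mesh across the medial-sagittal plane onto the other and
reporting the residual per-vertex deformation after rigid registration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._spatial import SurfaceQuery
from .errors import AmbiguityError, AnisotropyError, ParameterError, SplitError
from .mesh_core import Mesh, procrustes

__all__ = ["AngleMeasurement", "ift_direction", "insertion_angles",
           "theta_angle", "phi_angle", "mirror_fit", "MirrorFitResult"]

STANDARD_FRAME = "x:left-right y:ventral-dorsal z:caudal-cranial"


@dataclass
class AngleMeasurement:
    """Insertion angles of one inflow tract."""

    side: str
    v: np.ndarray
    theta_deg: float
    phi_deg: float
    frame_id: str = STANDARD_FRAME


def ift_direction(mesh: Mesh, region: np.ndarray) -> np.ndarray:
    """Principal direction of an elongated vertex region, oriented from the
    region centroid toward its distal (farthest) end."""
    region = np.asarray(region, dtype=np.int64)
    if len(region) < 10:
        raise ParameterError(
            f"IFT region needs at least 10 vertices, got {len(region)}")
    pts = mesh.vertices[region]
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts)
    eigvals, eigvecs = np.linalg.eigh(cov)
    spread_ratio = math.sqrt(eigvals[-1] / max(eigvals[-2], 1e-300))
    if spread_ratio < 1.5:
        raise AnisotropyError(
            f"region too isotropic: principal/secondary spread ratio "
            f"{spread_ratio:.2f} < 1.5")
    v = eigvecs[:, -1]
    distal = centred[np.argmax(np.linalg.norm(centred, axis=1))]
    if distal @ v < 0:
        v = -v
    return v / np.linalg.norm(v)


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64).reshape(3)
    n = np.linalg.norm(v)
    if n == 0:
        raise ParameterError("zero direction vector")
    return v / n


def theta_angle(v: np.ndarray, side: str) -> float:
    """Signed transverse-plane angle (deg) from +y; x flipped for the right
    side so left and right become directly comparable."""
    u = _unit(v)
    if side == "right":
        u = np.array([-u[0], u[1], u[2]])
    elif side != "left":
        raise ParameterError(f"side must be 'left' or 'right', got {side!r}")
    if math.hypot(u[0], u[1]) < 1e-12:
        raise AmbiguityError("direction has no xy-plane projection; theta undefined")
    return math.degrees(math.atan2(u[0], u[1]))


def phi_angle(v: np.ndarray) -> float:
    """Angle (deg) between v and the cranio-caudal +z axis, offset by -90 so
    transverse directions score 0."""
    u = _unit(v)
    return math.degrees(math.acos(np.clip(u[2], -1.0, 1.0))) - 90.0


def insertion_angles(v: np.ndarray, side: str) -> AngleMeasurement:
    """Both insertion angles of an IFT direction (raises when theta is
    undefined because v is parallel to z; use :func:`phi_angle` then)."""
    u = _unit(v)
    return AngleMeasurement(side=side, v=u, theta_deg=theta_angle(u, side),
                            phi_deg=phi_angle(u))


# -- mirror fit --------------------------------------------------------------

@dataclass
class MirrorFitResult:
    """Residual deformation after reflecting one side onto the other."""

    vertex_indices: np.ndarray   # vertices of the reflected sub-mesh
    distances: np.ndarray        # closest-point distance per reflected vertex
    mean: float
    max: float


def _submesh(mesh: Mesh, vertex_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(vertex indices, faces reindexed) of the faces fully inside the mask."""
    fmask = vertex_mask[mesh.faces].all(axis=1)
    faces = mesh.faces[fmask]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return used, remap[faces]


def mirror_fit(mesh: Mesh, plane_point: np.ndarray, plane_normal: np.ndarray,
               icp_iterations: int = 10) -> MirrorFitResult:
    """Reflect the negative side of ``mesh`` across the sagittal plane,
    rigidly register it onto the positive side (closest-point iteration) and
    report the per-vertex residual distances."""
    p0 = np.asarray(plane_point, dtype=np.float64).reshape(3)
    n = _unit(plane_normal)
    signed = (mesh.vertices - p0) @ n
    left_mask = signed < 0
    right_mask = signed > 0
    # vertices exactly on the plane belong to both sides
    lv, lf = _submesh(mesh, left_mask | (signed == 0))
    rv, rf = _submesh(mesh, right_mask | (signed == 0))
    if len(lf) == 0 or len(rf) == 0:
        raise SplitError("sagittal plane leaves one side empty")

    reflected = mesh.vertices[lv] - 2.0 * signed[lv, None] * n[None, :]
    query = SurfaceQuery(mesh.vertices[rv], rf)
    pts = reflected
    for _ in range(max(0, icp_iterations)):
        closest, dist, _ = query.closest(pts)
        tf, _ = procrustes(pts, closest, allow_scale=False)
        moved = tf.apply(pts)
        if np.abs(moved - pts).max() < 1e-12:
            pts = moved
            break
        pts = moved
    _, dist, _ = query.closest(pts)
    return MirrorFitResult(vertex_indices=lv, distances=dist,
                           mean=float(dist.mean()), max=float(dist.max()))
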