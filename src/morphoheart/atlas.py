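"""Densify an ordered keyframe collection into a smooth 3D+t mesh sequence.

Keyframes are stage meshes re-expressed on one shared connectivity (see
:mod:`morphoheart.correspondence`), each carrying a stage value (d1/d2).
Uniform linear interpolation inserts ``n_between`` frames per interval and a
Savitzky-Golay filter smooths every vertex trajectory over time so that the
transitions between stages are free of sharp kinks.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConsistencyError, ParameterError
from .mesh_core import Mesh, write_mesh

__all__ = ["KeyframeSequence", "DenseSequence", "interpolate",
           "smooth_trajectories", "export_sequence"]


@dataclass
class KeyframeSequence:
    """Ordered meshes sharing one connectivity, with per-keyframe stage values."""

    keyframes: list
    stage_values: np.ndarray | None = None
    landmark_sets: list | None = None

    def __post_init__(self) -> None:
        if not self.keyframes:
            return
        f0 = self.keyframes[0].faces
        for k, m in enumerate(self.keyframes):
            if m.n_vertices != self.keyframes[0].n_vertices or not np.array_equal(m.faces, f0):
                raise ConsistencyError(f"keyframe {k} does not share the reference connectivity")
        if self.stage_values is not None:
            self.stage_values = np.asarray(self.stage_values, dtype=np.float64)
            if len(self.stage_values) != len(self.keyframes):
                raise ConsistencyError("one stage value per keyframe required")
            if np.any(np.diff(self.stage_values) <= 0):
                raise ConsistencyError("stage values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.keyframes)


@dataclass
class DenseSequence:
    """A densified (and possibly smoothed) frame sequence."""

    frames: list
    stage_values: np.ndarray | None = None
    n_between: int = 0
    smoothed: bool = False

    def __len__(self) -> int:
        return len(self.frames)


def interpolate(seq: KeyframeSequence, n_between: int = 30) -> DenseSequence:
    """Uniform linear interpolation of ``n_between`` frames per interval.

    K keyframes yield K + (K-1) * n_between frames; keyframe slots carry the
    keyframes exactly and intermediate vertex positions are convex
    combinations of the bracketing keyframes.  Stage values, when present,
    are interpolated linearly alongside.
    """
    if len(seq) < 2:
        raise ParameterError("interpolation requires at least 2 keyframes")
    if n_between < 0:
        raise ParameterError("n_between must be >= 0")
    frames: list[Mesh] = []
    stages: list[float] = []
    faces = seq.keyframes[0].faces
    sv = seq.stage_values
    for k in range(len(seq) - 1):
        a, b = seq.keyframes[k], seq.keyframes[k + 1]
        frames.append(a.copy(name=f"frame{len(frames):04d}"))
        if sv is not None:
            stages.append(float(sv[k]))
        for m in range(1, n_between + 1):
            w = m / (n_between + 1)
            v = (1.0 - w) * a.vertices + w * b.vertices
            frames.append(Mesh(v, faces.copy(), name=f"frame{len(frames):04d}"))
            if sv is not None:
                stages.append(float((1.0 - w) * sv[k] + w * sv[k + 1]))
    frames.append(seq.keyframes[-1].copy(name=f"frame{len(frames):04d}"))
    if sv is not None:
        stages.append(float(sv[-1]))
    return DenseSequence(frames=frames,
                         stage_values=np.asarray(stages) if sv is not None else None,
                         n_between=n_between)


def smooth_trajectories(dense: DenseSequence, window: int = 7,
                        order: int = 3) -> DenseSequence:
    """Savitzky-Golay smoothing of every vertex trajectory over frame index.

    Polynomials of degree <= ``order`` pass through unchanged; the first and
    last frames are preserved exactly.
    """
    T = len(dense.frames)
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"window must be an odd count >= 3, got {window}")
    if order >= window:
        raise ParameterError(f"order ({order}) must be smaller than window ({window})")
    if window > T:
        raise ParameterError(f"window ({window}) exceeds frame count ({T})")
    traj = np.stack([f.vertices for f in dense.frames])  # (T, V, 3)
    sm = savgol_filter(traj, window_length=window, polyorder=order,
                       axis=0, mode="interp")
    sm[0] = traj[0]
    sm[-1] = traj[-1]
    faces = dense.frames[0].faces
    frames = [Mesh(sm[i], faces.copy(), name=dense.frames[i].name)
              for i in range(T)]
    return DenseSequence(frames=frames, stage_values=dense.stage_values,
                         n_between=dense.n_between, smoothed=True)


def export_sequence(dense: DenseSequence, out_dir: str | os.PathLike,
                    fmt: str = "ply") -> dict:
    """Write one mesh file per frame plus a JSON manifest mapping frame
    index to stage value.  Returns the manifest (with a warning flag when
    the sequence is empty)."""
    os.makedirs(out_dir, exist_ok=True)
    entries = []
    for i, frame in enumerate(dense.frames):
        fname = f"frame_{i:04d}.{fmt}"
        write_mesh(frame, os.path.join(out_dir, fname), fmt=fmt)
        stage = (float(dense.stage_values[i])
                 if dense.stage_values is not None else None)
        entries.append({"frame": i, "file": fname, "stage": stage})
    manifest = {"n_frames": len(dense.frames), "n_between": dense.n_between,
                "smoothed": dense.smoothed, "frames": entries}
    if not dense.frames:
        manifest["warning"] = "empty sequence: no frames written"
    tmp = os.path.join(out_dir, f".manifest-{os.getpid()}.tmp")
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=1)
    os.replace(tmp, os.path.join(out_dir, "manifest.json"))
    return manifest
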