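"""Morphometric staging: border-length measurements, clustering-based
parameter selection, dorsal-gap measurement and stage prediction.

The central staging quantity is d1/d2 — the length of the myocardium /
second-heart-field border (d1) over the myocardium / juxta-cardiac-field
border (d2), both measured along the outline of the tissue midsurface.  As
the crescent closes into a tube, d1 stretches dramatically while d2 remains
stable, so the ratio grows monotonically with developmental progression and
serves as a continuous morphometric clock.  Candidate staging parameters
are compared by k-means clustering quality (average silhouette coefficient)
over a range of group counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .errors import GeometryError, LandmarkError, ParameterError
from .mesh_core import (
    LandmarkSet,
    Mesh,
    boundary_subarc,
    geodesic_distance,
    outline_distance,
)

__all__ = ["StagingMeasurements", "ClusteringResult", "compute_measurements",
           "dorsal_gap", "cluster_and_score", "silhouette_mean",
           "select_parameter", "predict_stage", "StagePrediction"]


@dataclass
class StagingMeasurements:
    """Scalar staging measurements for one specimen (lengths in um)."""

    specimen: str = ""
    d1: float = np.nan
    d2: float = np.nan
    h: float = np.nan
    w: float = np.nan
    e1: float = np.nan
    e2: float = np.nan
    myo_width: float = np.nan
    gap: float = np.nan

    def _ratio(self, num: float, den: float) -> float:
        return num / den if den and den > 0 and np.isfinite(den) else np.nan

    @property
    def d1_over_d2(self) -> float:
        return self._ratio(self.d1, self.d2)

    @property
    def h_over_w(self) -> float:
        return self._ratio(self.h, self.w)

    @property
    def e1_over_e2(self) -> float:
        return self._ratio(self.e1, self.e2)

    def to_dict(self) -> dict:
        return {"specimen": self.specimen, "d1": self.d1, "d2": self.d2,
                "d1_d2": self.d1_over_d2, "h": self.h, "w": self.w,
                "h_w": self.h_over_w, "e1": self.e1, "e2": self.e2,
                "e1_e2": self.e1_over_e2, "myo_width": self.myo_width,
                "gap": self.gap}


@dataclass
class ClusteringResult:
    labels: np.ndarray
    centers: np.ndarray
    k: int
    s_bar: float


_D1_LANDMARKS = ("lm1", "lm2")
_D2_LANDMARKS = ("lm3", "lm4")
_LIP_LEFT = ("lm9", "lm7")
_LIP_RIGHT = ("lm8", "lm10")
_MYO_WIDTH_LANDMARKS = ("lm6", "lm11")


def compute_measurements(specimen, landmarks: LandmarkSet | None = None,
                         e1: float | None = None,
                         e2: float | None = None) -> StagingMeasurements:
    """Staging measurements of a landmarked midsurface.

    ``specimen`` is either a :class:`SynthSpecimen` or an open midsurface
    :class:`Mesh` (then ``landmarks`` is required).  e1/e2 (ventral
    protrusion and lateral extension of the primitive chamber) are accepted
    as precomputed scalars only.  Missing landmarks raise
    :class:`LandmarkError` naming the landmark, so a specimen can be skipped
    and staged manually, as done for partially differentiated crescents.
    """
    from .synthetic_embryo import SynthSpecimen

    if isinstance(specimen, SynthSpecimen):
        mesh = specimen.midsurface
        landmarks = specimen.landmarks if landmarks is None else landmarks
        if e1 is None:
            e1 = specimen.truth.get("e1")
        if e2 is None:
            e2 = specimen.truth.get("e2")
    else:
        mesh = specimen
        if landmarks is None:
            raise LandmarkError("landmarks required when passing a bare mesh")

    for name in (*_D1_LANDMARKS, *_D2_LANDMARKS):
        if name not in landmarks:
            raise LandmarkError(f"required landmark {name!r} missing")

    d1 = outline_distance(mesh, landmarks.point(_D1_LANDMARKS[0], mesh),
                          landmarks.point(_D1_LANDMARKS[1], mesh))
    d2 = outline_distance(mesh, landmarks.point(_D2_LANDMARKS[0], mesh),
                          landmarks.point(_D2_LANDMARKS[1], mesh))
    h = float(np.ptp(mesh.vertices[:, 2]))
    w = float(np.ptp(mesh.vertices[:, 0]))

    gap = np.nan
    if all(n in landmarks for n in (*_LIP_LEFT, *_LIP_RIGHT)):
        gap = dorsal_gap(mesh,
                         (landmarks.point(_LIP_LEFT[0], mesh),
                          landmarks.point(_LIP_LEFT[1], mesh)),
                         (landmarks.point(_LIP_RIGHT[0], mesh),
                          landmarks.point(_LIP_RIGHT[1], mesh)))
    myo_width = np.nan
    if all(n in landmarks for n in _MYO_WIDTH_LANDMARKS):
        myo_width = geodesic_distance(mesh,
                                      landmarks.vertex(_MYO_WIDTH_LANDMARKS[0]),
                                      landmarks.vertex(_MYO_WIDTH_LANDMARKS[1]))
    return StagingMeasurements(
        specimen=mesh.name, d1=d1, d2=d2, h=h, w=w,
        e1=np.nan if e1 is None else float(e1),
        e2=np.nan if e2 is None else float(e2),
        myo_width=myo_width, gap=gap)


def _sample_arc(mesh: Mesh, arc: np.ndarray, min_samples: int = 100) -> np.ndarray:
    """Points along a boundary arc: its vertices plus uniform subdivisions of
    every edge so that at least ``min_samples`` points result."""
    pts = mesh.vertices[arc]
    if len(pts) < 2:
        return pts
    n_edges = len(pts) - 1
    per_edge = max(2, int(np.ceil(min_samples / n_edges)))
    t = np.linspace(0.0, 1.0, per_edge, endpoint=False)
    seg = (pts[:-1, None, :] * (1.0 - t[None, :, None])
           + pts[1:, None, :] * t[None, :, None]).reshape(-1, 3)
    return np.concatenate([seg, pts[-1:]], axis=0)


def dorsal_gap(midsurface: Mesh, left_lip, right_lip) -> float:
    """Dorsal closure gap l: the shortest line joining the two dorsal lips.

    Each lip is the (shorter) boundary sub-arc between its two landmark
    points; both lips are subdivided densely and l is the minimum pairwise
    point distance.
    """
    arcs = []
    for (a, b) in (left_lip, right_lip):
        arc = boundary_subarc(midsurface, np.asarray(a), np.asarray(b))
        if len(arc) < 1:
            raise GeometryError("lip landmarks do not delimit a boundary sub-arc")
        arcs.append(_sample_arc(midsurface, arc))
    d = cdist(arcs[0], arcs[1])
    return float(d.min())


# -- clustering -------------------------------------------------------------

def silhouette_mean(values: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette coefficient s(i) = (b - a) / max(a, b) of a 1-D
    partition; members of singleton clusters score 0."""
    x = np.asarray(values, dtype=np.float64)
    lab = np.asarray(labels)
    ks = np.unique(lab)
    s = np.zeros(len(x))
    for i in range(len(x)):
        own = x[(lab == lab[i])]
        if len(own) == 1:
            s[i] = 0.0
            continue
        a = np.abs(own - x[i]).sum() / (len(own) - 1)
        b = min(np.abs(x[lab == k] - x[i]).mean() for k in ks if k != lab[i])
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(s.mean())


def cluster_and_score(values, k: int, seed: int = 0) -> ClusteringResult:
    """1-D k-means (best of 50 restarts from a fixed seed stream) with the
    average silhouette coefficient of the resulting partition."""
    x = np.asarray(values, dtype=np.float64).reshape(-1)
    n = len(x)
    if k < 2:
        raise ParameterError(f"silhouette scoring requires k >= 2, got k={k}")
    if k > n:
        raise ParameterError(f"k={k} exceeds the number of specimens ({n})")
    if len(np.unique(x)) < k:
        raise ParameterError(f"need at least k={k} distinct values")
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    labels = km.fit_predict(x[:, None])
    return ClusteringResult(labels=labels, centers=km.cluster_centers_.ravel(),
                            k=k, s_bar=silhouette_mean(x, labels))


def select_parameter(table: pd.DataFrame, k_range=range(2, 13),
                     seed: int = 0):
    """Pick the staging parameter and group count maximising the average
    silhouette coefficient.

    ``table`` holds one column per candidate parameter, one row per
    specimen.  Rows with missing values are dropped (listwise deletion,
    warned); all-constant columns are excluded with a warning.  Ties are
    broken by column order then by smaller k.  Returns
    ``(best parameter name, best k, score matrix DataFrame)``.
    """
    if table.shape[1] < 1:
        raise ParameterError("need at least one candidate parameter column")
    clean = table.dropna(axis=0)
    if len(clean) < len(table):
        warnings.warn(f"dropped {len(table) - len(clean)} specimens with "
                      "missing measurements (listwise deletion)")
    ks = [int(k) for k in k_range]
    scores = pd.DataFrame(index=ks, columns=list(table.columns), dtype=float)
    best = None  # (s_bar, col_pos, k_pos, name, k)
    for ci, col in enumerate(clean.columns):
        x = clean[col].to_numpy(dtype=np.float64)
        if np.ptp(x) == 0:
            warnings.warn(f"parameter {col!r} is constant; excluded")
            continue
        for ki, k in enumerate(ks):
            if k > len(x) or len(np.unique(x)) < k:
                continue
            res = cluster_and_score(x, k, seed=seed)
            scores.loc[k, col] = res.s_bar
            key = (-res.s_bar, ci, ki)
            if best is None or key < best[0]:
                best = (key, col, k)
    if best is None:
        raise ParameterError("no usable (parameter, k) combination")
    return best[1], best[2], scores


# -- stage prediction --------------------------------------------------------

@dataclass
class StagePrediction:
    d1_over_d2: float
    used_fallback: bool
    msg_stages: np.ndarray
    inverse_distances: np.ndarray


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def predict_stage(specimen_mesh: Mesh, msgs, specimen_landmarks: LandmarkSet,
                  measured_d1d2: float | None = None,
                  n_bracket: int = 5) -> StagePrediction:
    """Predict a specimen's d1/d2 stage from shape alone, against a sequence
    of mean-shape keyframes with known d1/d2 values.

    The seed keyframe is the one with stage value closest to the measured
    d1/d2 when given (otherwise the morphologically closest one); the two
    earlier and two later keyframes complete the bracket.  Morphological
    distances D to the bracket are converted to weights 1/(D + eps) and
    fitted with a Gaussian in stage value; the fitted peak (clamped to the
    bracket) is the prediction.  A failed fit falls back to the stage of the
    closest keyframe, flagged via ``used_fallback``.
    """
    from .correspondence import SurfaceMapper, landmark_pairs_from_sets
    from .mesh_core import procrustes
    from .shape_stats import morph_distance

    if msgs.stage_values is None:
        raise ParameterError("keyframe sequence must carry stage values")
    K = len(msgs)
    if K < 3:
        raise ParameterError(f"need at least 3 mean-shape keyframes, got {K}")
    stages = msgs.stage_values

    def morph_d(k: int) -> float:
        ref = msgs.keyframes[k]
        rp, tp, _ = landmark_pairs_from_sets(ref, specimen_mesh,
                                             msgs.landmark_sets[k],
                                             specimen_landmarks)
        mapper = SurfaceMapper(ref, specimen_mesh, rp, tp)
        pts, _ = mapper.map_points(ref.vertices)
        tf, _ = procrustes(pts, ref.vertices, allow_scale=False)
        return morph_distance(ref.vertices, tf.apply(pts), normalize_scale=True)

    if measured_d1d2 is not None:
        seed_k = int(np.argmin(np.abs(stages - measured_d1d2)))
        half = n_bracket // 2
        lo = max(0, min(seed_k - half, K - n_bracket))
        idx = np.arange(lo, min(K, lo + n_bracket))
        dists = np.array([morph_d(int(k)) for k in idx])
    else:
        all_d = np.array([morph_d(k) for k in range(K)])
        seed_k = int(np.argmin(all_d))
        half = n_bracket // 2
        lo = max(0, min(seed_k - half, K - n_bracket))
        idx = np.arange(lo, min(K, lo + n_bracket))
        dists = all_d[idx]

    eps = 1e-9 * np.mean([msgs.keyframes[int(k)].mean_edge_length() for k in idx])
    y = 1.0 / (dists + eps)
    x = stages[idx]

    used_fallback = False
    j = int(np.argmax(y))
    try:
        span = max(np.ptp(x), 1e-6)
        popt, _ = curve_fit(_gauss, x, y,
                            p0=[y[j], x[j], 0.5 * span],
                            maxfev=10000)
        mu = float(popt[1])
        if not np.isfinite(mu):
            raise RuntimeError("non-finite peak")
    except Exception:
        mu = float(x[j])
        used_fallback = True
    mu = float(np.clip(mu, x.min(), x.max()))
    return StagePrediction(d1_over_d2=mu, used_fallback=used_fallback,
                           msg_stages=x, inverse_distances=y)
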