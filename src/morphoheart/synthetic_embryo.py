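"""Synthetic landmarked crescent-to-tube specimens with known ground truth.

The generator emulates the myocardial midsurface of the forming heart tube
as a tapered partial cylinder: a cross-sectional circular arc of half-angle
``phi_max`` (just over 90 deg for an open crescent, approaching 180 deg for a
nearly closed tube) swept caudo-cranially with a linear radius taper.  The
two swept rim arcs play the role of the two myocardial borders (the border
with the second heart field cranially, the border with the juxta-cardiac
field caudally), so their length ratio d1/d2 equals the taper ratio exactly.
The free longitudinal edges are the dorsal lips; their separation realises a
prescribed dorsal gap.  Two narrow rectangular flaps extruded from the lips
near the caudal (venous) pole stand in for the inflow tracts: each flap's
long axis is a prescribed unit vector, so insertion angles have an exact
truth, and a signed left-right angle difference can be planted.

Vertex noise is a smooth random field applied along vertex normals: white
Gaussian noise diffused over the mesh graph and rescaled to the requested
standard deviation.  Spatially correlated displacement mimics the bulge-like
specimen-to-specimen variation seen in real embryos while leaving arc
lengths (and hence the staging truths) essentially unbiased.

All specimens generated with the same grid resolution share one vertex
connectivity, so ground-truth correspondence along a sequence is the
identity on vertex indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .mesh_core import LandmarkSet, Mesh

__all__ = ["SynthParams", "SynthSpecimen", "generate_specimen",
           "generate_sequence", "direction_from_angles"]

#: baseline caudal ventral radius of the crescent (um)
BASE_RADIUS = 100.0
#: symmetric baseline for the inflow-tract theta angle (deg)
THETA_BASE_DEG = 0.0
#: relative position (in u) of the caudal end of the measured lip arc
LIP_START_U = 0.36
#: caudal position (in u) of the inflow-tract band (venous pole region)
IFT_BAND_U = 0.2
#: number of grid rows spanned by the inflow-tract band
IFT_BAND_ROWS = 2
#: chord length of the inflow-tract facet as a fraction of the local radius
IFT_CHORD_FACTOR = 0.8
#: number of ventral columns flattened but excluded from the region, making
#: the region asymmetric so its distal (dorsal) end is farthest by margin
IFT_VENTRAL_TRIM_COLS = 2


def _default_d1_over_d2(t: float) -> float:
    return 1.0 + 1.4 * t


def _default_h_over_w(t: float) -> float:
    return 0.5 + 0.9 * t


def _default_gap(t: float) -> float:
    return 130.0 * (1.0 - t) + 8.0 * t


def _default_theta_asym(t: float) -> float:
    """Left-right divergence of the inflow-tract theta angle: zero until the
    linear-tube stage (d1/d2 ~ 1.55), growing to 20 deg by the looping stage."""
    d = _default_d1_over_d2(t)
    return 20.0 * min(1.0, max(0.0, (d - 1.55) / (2.4 - 1.55)))


@dataclass
class SynthParams:
    """Generator controls; any ``None`` field is filled from pseudo-time ``t``."""

    t: float = 0.5
    target_d1_over_d2: float | None = None
    target_h_over_w: float | None = None
    theta_asym_deg: float | None = None
    gap_width: float | None = None
    shell_thickness: float = 20.0
    noise_sigma: float = 2.0
    seed: int = 0
    n_u: int = 36
    n_v: int = 61
    radius: float = BASE_RADIUS

    def resolved(self) -> "SynthParams":
        p = replace(self)
        if not 0.0 <= p.t <= 1.0:
            raise ParameterError(f"t must lie in [0, 1], got {p.t}")
        if p.target_d1_over_d2 is None:
            p.target_d1_over_d2 = _default_d1_over_d2(p.t)
        if p.target_h_over_w is None:
            p.target_h_over_w = _default_h_over_w(p.t)
        if p.theta_asym_deg is None:
            p.theta_asym_deg = _default_theta_asym(p.t)
        if p.gap_width is None:
            p.gap_width = _default_gap(p.t)
        if min(p.target_d1_over_d2, p.target_h_over_w, p.gap_width,
               p.shell_thickness, p.radius) <= 0:
            raise ParameterError("all sizes and ratios must be positive")
        if p.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if p.n_u < 8 or p.n_v < 8:
            raise ParameterError(
                f"grid resolution too low: n_u={p.n_u}, n_v={p.n_v} (need >= 8)")
        return p


@dataclass
class SynthSpecimen:
    """One generated specimen: open midsurface, closed shell, landmarks and
    the exact measurement values the geometry was built to realise."""

    midsurface: Mesh
    shell: Mesh
    landmarks: LandmarkSet
    truth: dict
    params: SynthParams = field(repr=False, default=None)


def direction_from_angles(theta_deg: float, phi_deg: float, side: str) -> np.ndarray:
    """Unit vector whose insertion angles (theta, phi) equal the arguments.

    Inverse of :func:`morphoheart.asymmetry.insertion_angles`: phi is the
    angle to the cranio-caudal (+z) axis minus 90 deg, theta is measured in
    the transverse xy plane from +y (dorsal), with the x axis flipped for the
    right side so that mirror-symmetric vectors get equal theta.
    """
    polar = math.radians(90.0 + phi_deg)
    th = math.radians(theta_deg)
    v = np.array([math.sin(polar) * math.sin(th),
                  math.sin(polar) * math.cos(th),
                  math.cos(polar)])
    if side == "right":
        v[0] = -v[0]
    elif side != "left":
        raise ParameterError(f"side must be 'left' or 'right', got {side!r}")
    return v


def _grid_index(i: int, j: int, n_v: int) -> int:
    return i * n_v + j


#: fraction of the noise variance carried by independent per-vertex jitter;
#: the rest is a smooth (bulge-scale) random field
_FINE_NOISE_WEIGHT = 0.2


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Unit-std random displacement field on the parametric grid: a smooth
    Gaussian random field (bulge-like specimen-to-specimen variation, with a
    correlation length of several tens of micrometres) plus a small
    independent per-vertex jitter."""
    from scipy.ndimage import gaussian_filter

    coarse = gaussian_filter(rng.standard_normal(shape), sigma=(5.0, 9.0),
                             mode="nearest")
    s = coarse.std()
    if s > 0:
        coarse = coarse / s
    fine = rng.standard_normal(shape)
    w = _FINE_NOISE_WEIGHT
    return (math.sqrt(1.0 - w * w) * coarse + w * fine).ravel()


def generate_specimen(params: SynthParams) -> SynthSpecimen:
    """Build one landmarked specimen; deterministic for a fixed seed."""
    p = params.resolved()
    n_u, n_v = p.n_u, p.n_v
    r = p.target_d1_over_d2
    R0 = p.radius

    i_lip0 = int(round(LIP_START_U * (n_u - 1)))
    u_lip0 = i_lip0 / (n_u - 1)

    def radius_at(u: np.ndarray | float) -> np.ndarray | float:
        return R0 * (1.0 + (r - 1.0) * u)

    g = p.gap_width / (2.0 * radius_at(u_lip0))
    if not 0.0 < g < 0.995:
        raise ParameterError(
            f"gap_width {p.gap_width} not realisable with radius {R0} and "
            f"d1/d2 {r}: requires gap/(2 R(lip)) in (0, 1)")
    phi_max = math.pi - math.asin(g)

    u = np.arange(n_u) / (n_u - 1)
    v = -1.0 + 2.0 * np.arange(n_v) / (n_v - 1)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    Ru = radius_at(uu)
    phi = vv * phi_max
    x = Ru * np.sin(phi)
    y = -Ru * np.cos(phi)

    # -- inflow-tract facets ------------------------------------------------
    # Each inflow tract is a band of the surface near the venous pole that is
    # flattened onto a vertical chord plane whose in-plane horizontal
    # direction IS the prescribed insertion direction, plus a small tab
    # protruding in-plane beyond the facet on the dorsal side.  Because the
    # flattened vertices form a product grid on that plane (columns along the
    # chord line, rows along z), the principal axis of the region equals the
    # prescribed direction exactly, and the distal tab fixes its sign.
    theta_l = THETA_BASE_DEG
    theta_r = THETA_BASE_DEG - p.theta_asym_deg
    v_left = direction_from_angles(theta_l, 0.0, "left")
    v_right = direction_from_angles(theta_r, 0.0, "right")

    i_band0 = int(round(IFT_BAND_U * (n_u - 1)))
    i_band0 = max(1, min(i_band0, n_u - 2 - IFT_BAND_ROWS))
    band_rows = np.arange(i_band0, i_band0 + IFT_BAND_ROWS)
    R_band = radius_at(band_rows.mean() / (n_u - 1))

    # the overall height is set before faceting (the facet never carries the
    # lateral extremes, so it does not change the width)
    w_real = float(x.max() - x.min())
    height = p.target_h_over_w * w_real

    # cap the facet chord so its dent stays shallow relative to the vertical
    # extent of the band; a dent deeper than ~1/3 of its canyon would make
    # the inner wall of a 20-um shell fold into itself at early stages
    canyon = (IFT_BAND_ROWS + 2) * height / (n_u - 1)
    max_dent = 0.35 * canyon
    cos_half_min = max(1.0 - max_dent / R_band, 0.0)
    half = min(math.asin(min(0.999, IFT_CHORD_FACTOR / 2.0)),
               math.acos(cos_half_min))
    d0 = R_band * math.cos(half)
    phi_col = phi[0]  # column angles, shared by all rows
    col_step = 2.0 * phi_max / (n_v - 1)
    margin = col_step  # at least one untouched column inside each border

    ift_regions = {}
    for side, theta_side in (("left", theta_l), ("right", theta_r)):
        sign = -1.0 if side == "left" else 1.0
        phi_bar = sign * math.radians(90.0 + theta_side)
        lo = abs(phi_bar) - half
        hi = abs(phi_bar) + half
        if lo < margin or hi > phi_max - margin:
            raise ParameterError(
                f"inflow-tract facet ({side}) does not fit on the surface: "
                f"band [{math.degrees(lo):.1f}, {math.degrees(hi):.1f}] deg "
                f"vs available (0, {math.degrees(phi_max):.1f}) deg; "
                "reduce |theta_asym_deg| or widen the dorsal gap")
        in_window = (sign * phi_col >= lo) & (sign * phi_col <= hi)
        cols = np.nonzero(in_window)[0]
        rho = d0 / np.cos(phi_col[cols] - phi_bar)
        for i in band_rows:
            x[i, cols] = rho * np.sin(phi_col[cols])
            y[i, cols] = -rho * np.cos(phi_col[cols])
        # weighted transition rows soften the dent shoulders so the facet
        # remains a gentle feature of the tissue sheet
        xf = rho * np.sin(phi_col[cols])
        yf = -rho * np.cos(phi_col[cols])
        for i, w in ((band_rows[0] - 1, 0.6), (band_rows[-1] + 1, 0.6),
                     (band_rows[0] - 2, 0.25), (band_rows[-1] + 2, 0.25)):
            if 0 < i < n_u - 1:
                x[i, cols] = (1.0 - w) * x[i, cols] + w * xf
                y[i, cols] = (1.0 - w) * y[i, cols] + w * yf
        # region: drop the most ventral columns so the dorsal (distal) end
        # is unambiguously farthest from the centroid; with few columns the
        # trim falls back from two columns to one
        idx: list[int] = []
        for trim in range(IFT_VENTRAL_TRIM_COLS, 0, -1):
            region_ok = sign * phi_col[cols] >= lo + trim * col_step
            rcols = cols[region_ok]
            idx = [_grid_index(i, j, n_v) for i in band_rows for j in rcols]
            if len(idx) >= 10:
                break
        if len(idx) < 10:
            raise ParameterError(
                f"inflow-tract region ({side}) has only {len(idx)} vertices; "
                "increase n_v")
        ift_regions[side] = np.asarray(sorted(idx), dtype=np.int64)

    grid_xy = np.stack([x.ravel(), y.ravel()], axis=1)

    faces = []
    for i in range(n_u - 1):
        for j in range(n_v - 1):
            a = _grid_index(i, j, n_v)
            b = _grid_index(i + 1, j, n_v)
            c = _grid_index(i + 1, j + 1, n_v)
            d = _grid_index(i, j + 1, n_v)
            faces.append((a, b, c))
            faces.append((a, c, d))

    z = np.repeat(u * height, n_v)

    vertices = np.column_stack([grid_xy, z])
    faces = np.asarray(faces, dtype=np.int64)
    mid = Mesh(vertices, faces, name=f"synthetic-t{p.t:.3f}-seed{p.seed}")

    # -- noise ---------------------------------------------------------------
    if p.noise_sigma > 0:
        rng = np.random.default_rng(p.seed)
        amp = p.noise_sigma * _smooth_field(rng, (n_u, n_v))
        # taper to zero at the tissue borders: the borders (and hence the
        # staging truths defined on them) are anatomically sharp, while
        # specimen-to-specimen variability lives in the tissue interior
        ii, jj = np.meshgrid(np.arange(n_u), np.arange(n_v), indexing="ij")
        env = (np.clip(np.minimum(ii, n_u - 1 - ii) / 3.0, 0.0, 1.0)
               * np.clip(np.minimum(jj, n_v - 1 - jj) / 3.0, 0.0, 1.0)).ravel()
        amp = amp * env
        normals = mid.vertex_normals()
        mid = Mesh(mid.vertices + amp[:, None] * normals, mid.faces, mid.name)

    # -- shell ---------------------------------------------------------------
    shell = _offset_shell(mid, p.shell_thickness)

    # -- landmarks -----------------------------------------------------------
    j_mid = (n_v - 1) // 2
    lm = {
        "lm1": {"vertex": _grid_index(n_u - 1, 0, n_v)},          # d1 left end
        "lm2": {"vertex": _grid_index(n_u - 1, n_v - 1, n_v)},    # d1 right end
        "lm3": {"vertex": _grid_index(0, 0, n_v)},                # d2 left end
        "lm4": {"vertex": _grid_index(0, n_v - 1, n_v)},          # d2 right end
        "lm5": {"vertex": _grid_index((n_u - 1) // 2, j_mid, n_v)},
        "lm6": {"vertex": _grid_index(n_u - 1, j_mid, n_v)},      # cranial ventral mid
        "lm7": {"vertex": _grid_index(n_u - 1, 0, n_v)},          # left lip, cranial
        "lm8": {"vertex": _grid_index(n_u - 1, n_v - 1, n_v)},    # right lip, cranial
        "lm9": {"vertex": _grid_index(i_lip0, 0, n_v)},           # left lip, caudal
        "lm10": {"vertex": _grid_index(i_lip0, n_v - 1, n_v)},    # right lip, caudal
        "lm11": {"vertex": _grid_index(0, j_mid, n_v)},           # caudal ventral mid
        "lm12": {"vertex": _grid_index((n_u - 1) // 2, j_mid // 2, n_v)},
        # sparse interior landmark grid used for surface-map computation
        **{f"lm{13 + 5 * a + b}":
           {"vertex": _grid_index(int(round((0.25 + 0.25 * a) * (n_u - 1))),
                                  int(round((0.1 + 0.2 * b) * (n_v - 1))), n_v)}
           for a in range(3) for b in range(5)},
        "ift_left": {"vertices": ift_regions["left"].tolist()},
        "ift_right": {"vertices": ift_regions["right"].tolist()},
        "ift_left_dir": {"vector": v_left.tolist()},
        "ift_right_dir": {"vector": v_right.tolist()},
    }
    landmarks = LandmarkSet(entries=lm)

    # -- exact truths --------------------------------------------------------
    seg = 2.0 * phi_max / (n_v - 1)
    d2_true = (n_v - 1) * 2.0 * radius_at(0.0) * math.sin(seg / 2.0)
    d1_true = (n_v - 1) * 2.0 * radius_at(1.0) * math.sin(seg / 2.0)
    myo_width_true = math.hypot(height, R0 * (r - 1.0))
    R_mid = radius_at(0.5)
    e1_true = R_mid * (1.0 - math.cos(phi_max))
    e2_true = w_real / 2.0
    truth = {
        "t": p.t,
        "d1": d1_true,
        "d2": d2_true,
        "d1_over_d2": d1_true / d2_true,
        "h": height,
        "w": w_real,
        "h_over_w": p.target_h_over_w,
        "gap": p.gap_width,
        "myo_width": myo_width_true,
        "e1": e1_true,
        "e2": e2_true,
        "e1_over_e2": e1_true / e2_true,
        "theta_left_deg": theta_l,
        "theta_right_deg": theta_r,
        "theta_asym_deg": p.theta_asym_deg,
        "phi_left_deg": 0.0,
        "phi_right_deg": 0.0,
        "v_left": v_left,
        "v_right": v_right,
        "phi_max_rad": phi_max,
        "shell_thickness": p.shell_thickness,
        "noise_sigma": p.noise_sigma,
        "seed": p.seed,
    }
    return SynthSpecimen(midsurface=mid, shell=shell, landmarks=landmarks,
                         truth=truth, params=p)


def _offset_shell(mid: Mesh, thickness: float) -> Mesh:
    """Closed genus-0 shell: midsurface offset +-thickness/2 along vertex
    normals, the two walls joined by a strip of quads along the boundary."""
    normals = mid.vertex_normals()
    half = 0.5 * thickness
    outer = mid.vertices + half * normals
    inner = mid.vertices - half * normals
    nV = mid.n_vertices
    f_outer = mid.faces
    f_inner = mid.faces[:, ::-1] + nV

    directed = set(map(tuple, mid.edges()))
    strip = []
    for a, b in mid.boundary_edges():
        a, b = int(a), int(b)
        if (a, b) not in directed:
            a, b = b, a
        strip.append((b, a, a + nV))
        strip.append((b, a + nV, b + nV))
    faces = np.concatenate([f_outer, f_inner,
                            np.asarray(strip, dtype=np.int64)], axis=0)
    shell = Mesh(np.concatenate([outer, inner], axis=0), faces,
                 name=mid.name + "-shell")
    if shell.to_trimesh().volume < 0:
        shell = Mesh(shell.vertices, shell.faces[:, ::-1].copy(), shell.name)
    return shell


def generate_sequence(n: int | None, t_values: Sequence[float] | None,
                      base: SynthParams) -> list[SynthSpecimen]:
    """Generate a staged family of specimens sharing one grid connectivity.

    ``t_values`` must be sorted within [0, 1]; if omitted, ``n`` evenly
    spaced pseudo-times are used.  Specimen k gets seed ``base.seed + k`` so
    noise realisations differ while the truth trajectory is seed-free.
    """
    if t_values is None:
        if n is None or n < 1:
            raise ParameterError("need n >= 1 when t_values is not given")
        t_values = np.linspace(0.0, 1.0, n)
    t_values = np.asarray(list(t_values), dtype=np.float64)
    if np.any(np.diff(t_values) < 0):
        raise ParameterError("t_values must be sorted ascending")
    if np.any((t_values < 0) | (t_values > 1)):
        raise ParameterError("t_values must lie in [0, 1]")
    if n is not None and n != len(t_values):
        raise ParameterError(f"n={n} disagrees with len(t_values)={len(t_values)}")
    out = []
    for k, t in enumerate(t_values):
        pk = replace(base, t=float(t), seed=base.seed + k)
        out.append(generate_specimen(pk))
    return out
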