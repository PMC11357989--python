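"""Staging measurements, dorsal gap, clustering and stage prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from morphoheart.errors import LandmarkError, ParameterError
from morphoheart.mesh_core import LandmarkSet, Mesh, outline_distance
from morphoheart.staging import (
    cluster_and_score,
    compute_measurements,
    dorsal_gap,
    predict_stage,
    select_parameter,
    silhouette_mean,
)
from morphoheart.synthetic_embryo import SynthParams, generate_sequence
from morphoheart.atlas import KeyframeSequence

from conftest import specimen


# -- measurements ------------------------------------------------------------

@pytest.mark.parametrize("t,noise,tol", [(0.25, 0.0, 1e-6), (0.75, 0.0, 1e-6),
                                         (0.25, 2.0, 0.02), (0.75, 2.0, 0.02)])
def test_measurement_truth_recovery(t, noise, tol):
    sp = specimen(t, noise=noise, seed=13)
    ms = compute_measurements(sp)
    assert ms.d1_over_d2 == pytest.approx(sp.truth["d1_over_d2"], rel=tol)
    assert ms.h_over_w == pytest.approx(sp.truth["h_over_w"], rel=tol)
    assert ms.gap == pytest.approx(sp.truth["gap"], rel=tol)


def test_symmetric_specimen_half_outlines_agree():
    sp = specimen(0.3, noise=0.0, theta_asym_deg=0.0)
    m, lm = sp.midsurface, sp.landmarks
    left = outline_distance(m, lm.point("lm1", m), lm.point("lm6", m))
    right = outline_distance(m, lm.point("lm2", m), lm.point("lm6", m))
    assert left == pytest.approx(right, rel=0.01)


def test_missing_landmark_raises_by_name():
    sp = specimen(0.3)
    lms = LandmarkSet(entries={k: v for k, v in sp.landmarks.entries.items()
                               if k != "lm1"})
    with pytest.raises(LandmarkError, match="lm1"):
        compute_measurements(sp.midsurface, lms)


def test_ratios_invariant_under_rigid_motion_and_scale():
    sp = specimen(0.6, noise=2.0, seed=4)
    ms = compute_measurements(sp)
    scaled = Mesh(3.0 * sp.midsurface.vertices, sp.midsurface.faces)
    ms2 = compute_measurements(scaled, sp.landmarks)
    assert ms2.d1_over_d2 == pytest.approx(ms.d1_over_d2, rel=1e-9)
    assert ms2.h_over_w == pytest.approx(ms.h_over_w, rel=1e-9)


# -- dorsal gap --------------------------------------------------------------

def u_channel(half_gap=1.0, depth=1.0, length=4.0, nz=9, taper=0.0):
    """Open U-channel: two vertical lips at x = +-(half_gap + taper*z)."""
    zs = np.linspace(0.0, length, nz)
    cross = [(-1.0, depth), (-1.0, 0.0), (1.0, 0.0), (1.0, depth)]
    verts = np.array([[cx * (half_gap + taper * z), y, z]
                      for z in zs for cx, y in cross])
    faces = []
    for i in range(nz - 1):
        for j in range(3):
            a = i * 4 + j
            b = (i + 1) * 4 + j
            c = (i + 1) * 4 + j + 1
            d = i * 4 + j + 1
            faces += [(a, b, c), (a, c, d)]
    return Mesh(verts, np.asarray(faces))


def test_dorsal_gap_parallel_lips():
    m = u_channel(half_gap=1.0)
    top_left_a = m.vertices[0]          # (-1, depth, 0)
    top_left_b = m.vertices[(9 - 1) * 4]
    top_right_a = m.vertices[3]
    top_right_b = m.vertices[(9 - 1) * 4 + 3]
    assert dorsal_gap(m, (top_left_a, top_left_b),
                      (top_right_a, top_right_b)) == pytest.approx(2.0)


def test_dorsal_gap_touching_lips():
    m = u_channel(half_gap=1.0, taper=-0.25)  # lips meet at z = 4
    l = dorsal_gap(m, (m.vertices[0], m.vertices[32]),
                   (m.vertices[3], m.vertices[35]))
    assert l == pytest.approx(0.0, abs=1e-12)


def test_dorsal_gap_matches_brute_force_on_tapered_lips():
    m = u_channel(half_gap=0.4, taper=0.3)
    lips = ((m.vertices[0], m.vertices[32]), (m.vertices[3], m.vertices[35]))
    l = dorsal_gap(m, *lips)
    # brute force: dense sampling of both analytic lip segments
    z = np.linspace(0, 4, 200)
    left = np.column_stack([-(0.4 + 0.3 * z), np.full_like(z, 1.0), z])
    right = np.column_stack([+(0.4 + 0.3 * z), np.full_like(z, 1.0), z])
    from scipy.spatial.distance import cdist
    assert l == pytest.approx(cdist(left, right).min(), rel=1e-6)


def test_dorsal_gap_truth_on_specimen():
    sp = specimen(0.55, noise=2.0, seed=19)
    ms = compute_measurements(sp)
    assert ms.gap == pytest.approx(sp.truth["gap"], rel=0.02)


# -- clustering --------------------------------------------------------------

def test_silhouette_perfectly_separated():
    res = cluster_and_score([0, 0, 0, 10, 10, 10], 2, seed=0)
    assert res.s_bar == pytest.approx(1.0)


def test_silhouette_hand_computed_example():
    """{0,1,10} with clusters {0,1},{10}: s = (0.9 + 8/9 + 0)/3."""
    res = cluster_and_score([0.0, 1.0, 10.0], 2, seed=0)
    expected = (0.9 + 8.0 / 9.0 + 0.0) / 3.0
    assert res.s_bar == pytest.approx(expected, abs=1e-12)


def test_cluster_centers():
    res = cluster_and_score([0.0, 0.0, 10.0, 10.0], 2, seed=0)
    assert sorted(np.round(res.centers, 9)) == [0.0, 10.0]


def test_silhouette_matches_sklearn_without_singletons():
    from sklearn.metrics import silhouette_score

    rng = np.random.default_rng(3)
    x = np.concatenate([rng.normal(0, 1, 15), rng.normal(8, 1, 15),
                        rng.normal(20, 1, 10)])
    res = cluster_and_score(x, 3, seed=0)
    assert res.s_bar == pytest.approx(
        silhouette_score(x[:, None], res.labels), abs=1e-9)


@pytest.mark.parametrize("vals,k", [([1, 2, 3], 1), ([1, 2], 3), ([1, 1, 1], 2)])
def test_cluster_parameter_errors(vals, k):
    with pytest.raises(ParameterError):
        cluster_and_score(vals, k, seed=0)


def test_select_parameter_picks_planted_column():
    rng = np.random.default_rng(0)
    centers = np.arange(10) * 20.0
    informative = np.repeat(centers, 5) + rng.normal(0, 1.0, 50)
    noise = rng.uniform(0, 180, 50)
    table = pd.DataFrame({"planted": informative, "noise": noise})
    name, k, scores = select_parameter(table, range(2, 12), seed=0)
    assert name == "planted"
    assert scores.loc[k, "planted"] >= scores["noise"].max()


def test_select_parameter_tie_breaks_by_column_order():
    vals = np.array([0.0, 0.1, 5.0, 5.1, 10.0, 10.1])
    table = pd.DataFrame({"first": vals, "second": vals.copy()})
    name, _, _ = select_parameter(table, range(2, 4), seed=0)
    assert name == "first"


def test_select_parameter_single_column_and_constant_excluded():
    vals = np.array([0.0, 0.1, 5.0, 5.1, 10.0, 10.1])
    table = pd.DataFrame({"only": vals, "flat": np.ones(6)})
    with pytest.warns(UserWarning, match="constant"):
        name, k, _ = select_parameter(table, range(2, 4), seed=0)
    assert name == "only"


# -- staged-sequence properties ----------------------------------------------

def test_measured_ratio_rank_order_matches_time():
    seq0 = generate_sequence(11, None, SynthParams(seed=8, noise_sigma=0.0))
    r0 = [compute_measurements(sp).d1_over_d2 for sp in seq0]
    assert spearmanr(r0, np.arange(11)).statistic == pytest.approx(1.0)
    seq2 = generate_sequence(11, None, SynthParams(seed=8, noise_sigma=2.0))
    r2 = [compute_measurements(sp).d1_over_d2 for sp in seq2]
    assert spearmanr(r2, np.arange(11)).statistic >= 0.95


# -- stage prediction --------------------------------------------------------

@pytest.fixture(scope="module")
def msg_sequence():
    seq = generate_sequence(6, None, SynthParams(seed=3, noise_sigma=0.0))
    return seq, KeyframeSequence(
        [s.midsurface for s in seq],
        stage_values=[s.truth["d1_over_d2"] for s in seq],
        landmark_sets=[s.landmarks for s in seq])


def test_predict_exact_copy_of_keyframe(msg_sequence):
    seq, kfs = msg_sequence
    pred = predict_stage(seq[3].midsurface, kfs, seq[3].landmarks,
                         measured_d1d2=seq[3].truth["d1_over_d2"])
    assert pred.d1_over_d2 == pytest.approx(seq[3].truth["d1_over_d2"],
                                            abs=1e-3)


def test_predict_between_keyframes(msg_sequence):
    seq, kfs = msg_sequence
    sp = specimen(0.5, noise=0.0, seed=40)  # between keyframes t=0.4, t=0.6
    ms = compute_measurements(sp)
    pred = predict_stage(sp.midsurface, kfs, sp.landmarks,
                         measured_d1d2=ms.d1_over_d2)
    lo = seq[2].truth["d1_over_d2"]
    hi = seq[3].truth["d1_over_d2"]
    assert lo - 1e-9 <= pred.d1_over_d2 <= hi + 1e-9


def test_predict_needs_three_keyframes(msg_sequence):
    seq, _ = msg_sequence
    short = KeyframeSequence([s.midsurface for s in seq[:2]],
                             stage_values=[1.0, 2.0],
                             landmark_sets=[s.landmarks for s in seq[:2]])
    with pytest.raises(ParameterError):
        predict_stage(seq[0].midsurface, short, seq[0].landmarks)
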