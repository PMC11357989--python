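"""Mean shapes, per-vertex variability, morphological distances, medoids."""

import numpy as np
import pytest

from morphoheart.correspondence import CorrespondenceMap
from morphoheart.errors import ConsistencyError, ParameterError
from morphoheart.mesh_core import Mesh, RigidTransform
from morphoheart.shape_stats import (
    align_group,
    centroid_size,
    mean_shape,
    medoid,
    morph_distance,
)

from conftest import specimen


def _rot(deg, axis=2):
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    m = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    m[i, i] = m[j, j] = c
    m[i, j], m[j, i] = -s, s
    return m


def _map_for(ref: Mesh, points: np.ndarray) -> CorrespondenceMap:
    return CorrespondenceMap(reference=ref.name, target="", points=points)


@pytest.fixture(scope="module")
def ref_mesh():
    return specimen(0.5, noise=0.0, seed=1).midsurface


# -- align_group -------------------------------------------------------------

def test_align_group_undoes_translation_and_rotation(ref_mesh):
    moved1 = ref_mesh.vertices + np.array([10.0, -5.0, 3.0])
    moved2 = ref_mesh.vertices @ _rot(180.0).T + np.array([1.0, 1.0, 1.0])
    aligned = align_group(ref_mesh, [ref_mesh, ref_mesh],
                          [_map_for(ref_mesh, moved1),
                           _map_for(ref_mesh, moved2)])
    for pts in aligned:
        assert np.abs(pts - ref_mesh.vertices).max() < 1e-6


def test_align_group_count_mismatch_raises(ref_mesh):
    bad = _map_for(ref_mesh, ref_mesh.vertices[:10])
    with pytest.raises(ConsistencyError):
        align_group(ref_mesh, [ref_mesh], [bad])


def test_align_group_wrong_target_raises(ref_mesh):
    cmap = CorrespondenceMap(reference=ref_mesh.name, target="other-mesh",
                             points=ref_mesh.vertices.copy())
    with pytest.raises(ConsistencyError):
        align_group(ref_mesh, [ref_mesh], [cmap])


# -- mean shape and variability ----------------------------------------------

def test_mean_of_identical_shapes_has_zero_sd(ref_mesh):
    res = mean_shape([ref_mesh.vertices.copy() for _ in range(5)], ref_mesh)
    assert np.abs(res.mean_mesh.vertices - ref_mesh.vertices).max() < 1e-12
    assert res.per_vertex_sd.max() == 0.0


def test_single_vertex_displacement_gives_unit_sd(ref_mesh):
    """Two shapes, one vertex displaced 2 um along x: population covariance
    of {-1, +1} along x has largest eigenvalue 1, so sd = 1 um there."""
    a = ref_mesh.vertices.copy()
    b = ref_mesh.vertices.copy()
    b[7, 0] += 2.0
    res = mean_shape([a, b], ref_mesh)
    assert res.per_vertex_sd[7] == pytest.approx(1.0, abs=1e-12)
    mask = np.ones(len(a), dtype=bool)
    mask[7] = False
    assert res.per_vertex_sd[mask].max() == 0.0


def test_sd_matches_independent_svd_oracle(ref_mesh):
    rng = np.random.default_rng(5)
    sets = [ref_mesh.vertices + rng.normal(0, 1.5, ref_mesh.vertices.shape)
            for _ in range(6)]
    res = mean_shape(sets, ref_mesh)
    stack = np.stack(sets)
    centred = stack - stack.mean(axis=0)
    # oracle: singular values of the per-vertex (n x 3) data matrix
    for v in rng.integers(0, ref_mesh.n_vertices, size=20):
        sv = np.linalg.svd(centred[:, v, :], compute_uv=False)
        assert res.per_vertex_sd[v] == pytest.approx(
            sv[0] / np.sqrt(len(sets)), abs=1e-9)


def test_mean_with_single_member_has_undefined_sd(ref_mesh):
    res = mean_shape([ref_mesh.vertices], ref_mesh)
    assert np.isnan(res.per_vertex_sd).all()
    assert np.abs(res.mean_mesh.vertices - ref_mesh.vertices).max() == 0.0


def test_mean_of_rigidly_moved_copies_recovers_shape(ref_mesh):
    rng = np.random.default_rng(11)
    maps = []
    for _ in range(4):
        tf = RigidTransform(_rot(float(rng.uniform(-90, 90)),
                                 axis=int(rng.integers(3))),
                            rng.normal(0, 50, 3))
        maps.append(_map_for(ref_mesh, tf.apply(ref_mesh.vertices)))
    aligned = align_group(ref_mesh, [ref_mesh] * 4, maps)
    res = mean_shape([ref_mesh.vertices] + aligned, ref_mesh)
    assert np.abs(res.mean_mesh.vertices - ref_mesh.vertices).max() < 1e-6
    assert res.per_vertex_sd.max() < 1e-6


def test_sd_invariant_under_common_rigid_motion(ref_mesh):
    rng = np.random.default_rng(2)
    sets = [ref_mesh.vertices + rng.normal(0, 1.0, ref_mesh.vertices.shape)
            for _ in range(4)]
    res1 = mean_shape(sets, ref_mesh)
    tf = RigidTransform(_rot(37.0), np.array([4.0, 5.0, 6.0]))
    res2 = mean_shape([tf.apply(s) for s in sets], ref_mesh)
    assert np.abs(res1.per_vertex_sd - res2.per_vertex_sd).max() < 1e-9


# -- morphological distance --------------------------------------------------

def test_morph_distance_basics():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(50, 3))
    assert morph_distance(a, a) == 0.0
    assert morph_distance(a, a + np.array([3.0, 4.0, 0.0])) == pytest.approx(5.0)
    assert morph_distance(a, 2.0 * a, normalize_scale=True) < 1e-9
    with pytest.raises(ConsistencyError):
        morph_distance(a, a[:-1])


def test_morph_distance_symmetry_and_triangle_inequality():
    rng = np.random.default_rng(1)
    a, b, c = (rng.normal(size=(30, 3)) for _ in range(3))
    assert morph_distance(a, b) == pytest.approx(morph_distance(b, a))
    assert morph_distance(a, c) <= morph_distance(a, b) + morph_distance(b, c)


# -- medoid ------------------------------------------------------------------

def test_medoid_exhaustive_oracle():
    rng = np.random.default_rng(4)
    A = rng.normal(size=(40, 3))
    group = [A, A + rng.normal(0, 0.01, A.shape), A + 5.0 * rng.normal(size=A.shape)]
    idx, q = medoid(group, normalize_scale=False)
    # oracle: exhaustive accumulated pairwise distances
    n = len(group)
    q_ref = np.array([sum(morph_distance(group[i], group[j])
                          for j in range(n) if j != i) for i in range(n)])
    assert np.abs(q - q_ref).max() < 1e-12
    assert idx == int(np.argmin(q_ref))
    assert idx in (0, 1)


def test_medoid_all_identical_tie_rule():
    A = np.random.default_rng(0).normal(size=(20, 3))
    idx, q = medoid([A.copy() for _ in range(4)])
    assert idx == 0
    assert np.abs(q).max() == 0.0


def test_medoid_with_scaling_treats_scaled_copy_as_equal():
    rng = np.random.default_rng(6)
    A = rng.normal(size=(30, 3))
    B = A + 3.0 * rng.normal(size=A.shape)
    idx, _ = medoid([A, 2.0 * A, B], normalize_scale=True)
    assert idx in (0, 1)


def test_medoid_invariant_to_ordering():
    rng = np.random.default_rng(7)
    group = [rng.normal(size=(25, 3)) for _ in range(5)]
    idx1, q1 = medoid(group)
    perm = [3, 1, 4, 0, 2]
    idx2, q2 = medoid([group[i] for i in perm])
    assert perm[idx2] == idx1
    assert np.abs(np.asarray(q2) - np.asarray(q1)[perm]).max() < 1e-9


def test_medoid_needs_two_members():
    with pytest.raises(ParameterError):
        medoid([np.zeros((5, 3))])


def test_centroid_size():
    pts = np.array([[1.0, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]])
    assert centroid_size(pts) == pytest.approx(1.0)
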