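"""Shape representation, Procrustes alignment, shape PCA and pose transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aamfit as A
from aamfit.shape import (IMAGE_FRAME, MODEL_FRAME, compose_pose,
                          project_shape, transform_points)

TRIANGLE = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 3.0]])


def _shape(pts):
    return A.LandmarkShape.from_points(np.asarray(pts, dtype=float), MODEL_FRAME)


def _similarity(pts, scale, theta, t):
    c, s = scale * np.cos(theta), scale * np.sin(theta)
    M = np.array([[c, -s], [s, c]])
    return pts @ M.T + t


# ---------------------------------------------------------------------------
# LandmarkShape representation

def test_layout_differs_between_frames():
    pts = np.array([[1.0, 2.0], [3.0, 4.0]])
    m = A.LandmarkShape.from_points(pts, MODEL_FRAME)
    i = A.LandmarkShape.from_points(pts, IMAGE_FRAME)
    assert np.array_equal(m.coords, [1, 3, 2, 4])      # (x1..xn, y1..yn)
    assert np.array_equal(i.coords, [1, 2, 3, 4])      # interleaved
    assert np.array_equal(m.points(), pts)
    assert np.array_equal(i.points(), pts)


@pytest.mark.parametrize("bad", [[1.0, 2.0, 3.0], [np.nan, 0.0]])
def test_invalid_coords_rejected(bad):
    with pytest.raises(ValueError):
        A.LandmarkShape(np.array(bad))


# ---------------------------------------------------------------------------
# Procrustes alignment

def test_single_shape_aligns_to_centered_unit_norm():
    aligned, mean = A.procrustes_align([_shape(TRIANGLE)])
    pts = aligned[0].points()
    assert np.allclose(pts.mean(axis=0), 0, atol=1e-12)
    assert np.isclose(np.linalg.norm(pts), 1.0)
    assert np.allclose(pts, mean.points(), atol=1e-12)


def test_similarity_invariance_of_pair():
    a = TRIANGLE
    b = _similarity(TRIANGLE, 2.0, np.deg2rad(30), [5.0, -1.0])
    aligned, _ = A.procrustes_align([_shape(a), _shape(b)])
    assert np.allclose(aligned[0].points(), aligned[1].points(), atol=1e-8)


def _gpa_oracle(point_sets, iters=200):
    """Brute-force alternating alignment with an explicit 4-parameter solve."""
    centered = [p - p.mean(axis=0) for p in point_sets]
    ref = centered[0] / np.linalg.norm(centered[0])
    for _ in range(iters):
        fitted = []
        for p in centered:
            # least squares for (a, b, tx, ty) in x' = a x - b y + tx, ...
            n = len(p)
            M = np.zeros((2 * n, 4))
            M[:n, 0], M[:n, 1], M[:n, 2] = p[:, 0], -p[:, 1], 1.0
            M[n:, 0], M[n:, 1], M[n:, 3] = p[:, 1], p[:, 0], 1.0
            rhs = np.concatenate([ref[:, 0], ref[:, 1]])
            a, b, tx, ty = np.linalg.lstsq(M, rhs, rcond=None)[0]
            fitted.append(np.column_stack([a * p[:, 0] - b * p[:, 1] + tx,
                                           b * p[:, 0] + a * p[:, 1] + ty]))
        new = np.mean(fitted, axis=0)
        new -= new.mean(axis=0)
        new /= np.linalg.norm(new)
        if np.linalg.norm(new - ref) < 1e-14:
            break
        ref = new
    # same orientation gauge as the implementation: farthest landmark on +x
    z = ref[:, 0] + 1j * ref[:, 1]
    anchor = z[np.argmax(np.abs(z))]
    z = z * np.conj(anchor) / abs(anchor)
    return np.column_stack([z.real, z.imag])


def test_mean_matches_bruteforce_oracle(rng):
    square = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
    sets = []
    for _ in range(5):
        noisy = square + rng.normal(0, 0.05, square.shape)
        sets.append(_similarity(noisy, rng.uniform(0.5, 2), rng.uniform(0, 6),
                                rng.normal(0, 3, 2)))
    _, mean = A.procrustes_align([_shape(p) for p in sets])
    oracle = _gpa_oracle(sets)
    assert np.allclose(mean.points(), oracle, atol=1e-6)


def test_procrustes_idempotent(rng):
    sets = [TRIANGLE + rng.normal(0, 0.1, TRIANGLE.shape) for _ in range(4)]
    aligned, _ = A.procrustes_align([_shape(p) for p in sets])
    again, _ = A.procrustes_align(aligned)
    for a, b in zip(aligned, again):
        assert np.allclose(a.coords, b.coords, atol=1e-8)


def test_alignment_invariant_to_common_pretransform(rng):
    sets = [TRIANGLE + rng.normal(0, 0.1, TRIANGLE.shape) for _ in range(4)]
    aligned1, _ = A.procrustes_align([_shape(p) for p in sets])
    moved = [_similarity(p, 1.7, 0.9, [10.0, -4.0]) for p in sets]
    aligned2, _ = A.procrustes_align([_shape(p) for p in moved])
    for a, b in zip(aligned1, aligned2):
        assert np.allclose(a.coords, b.coords, atol=1e-6)


def test_procrustes_errors():
    with pytest.raises(ValueError):
        A.procrustes_align([])
    with pytest.raises(ValueError, match="points"):
        A.procrustes_align([_shape(TRIANGLE), _shape(TRIANGLE[:2])])
    degenerate = _shape(np.ones((3, 2)))
    with pytest.raises(ValueError, match="shape 1"):
        A.procrustes_align([_shape(TRIANGLE), degenerate])


# ---------------------------------------------------------------------------
# shape PCA

def test_identical_shapes_give_no_modes():
    shapes = [_shape(TRIANGLE)] * 3
    model = A.build_shape_pca(shapes, variance_retained=0.98)
    assert model.n_modes == 0
    assert model.eigenvalues.size == 0


def test_rank_one_data_single_mode(rng):
    base = TRIANGLE.flatten(order="F")   # model layout
    d = rng.normal(size=base.size)
    d /= np.linalg.norm(d)
    shapes = [A.LandmarkShape(base + t * d) for t in (-1, -0.5, 0.5, 1)]
    model = A.build_shape_pca(shapes, variance_retained=1.0)
    assert model.n_modes == 1
    cross = abs(model.Ps[:, 0] @ d)
    assert np.isclose(cross, 1.0, atol=1e-10)


def test_eigenvalues_match_direct_eigendecomposition(rng):
    base = rng.normal(size=12)
    modes = np.linalg.qr(rng.normal(size=(12, 2)))[0]
    coords = [base + modes @ rng.normal(0, [2.0, 0.5]) for _ in range(20)]
    X = np.stack(coords)
    model = A.build_shape_pca([A.LandmarkShape(c) for c in coords],
                              variance_retained=1.0)
    ev = np.linalg.eigvalsh(np.cov(X.T))[::-1]
    assert np.allclose(model.eigenvalues, ev[:model.n_modes], atol=1e-8)


def test_full_variance_reconstructs_training_shapes(rng):
    coords = [rng.normal(size=10) for _ in range(6)]
    shapes = [A.LandmarkShape(c) for c in coords]
    model = A.build_shape_pca(shapes, variance_retained=1.0)
    for s in shapes:
        b = project_shape(model, s)
        rec = A.shape_from_params(model, b)
        assert np.allclose(rec.coords, s.coords, atol=1e-8)


def test_shape_from_params_examples(rng):
    coords = [rng.normal(size=10) for _ in range(6)]
    model = A.build_shape_pca([A.LandmarkShape(c) for c in coords], 1.0)
    assert np.allclose(A.shape_from_params(model, np.zeros(model.n_modes)).coords,
                       model.s0.coords)
    e1 = np.zeros(model.n_modes)
    e1[0] = 1.0
    assert np.allclose(A.shape_from_params(model, e1).coords,
                       model.s0.coords + model.Ps[:, 0])
    b = rng.normal(size=model.n_modes)
    naive = model.s0.coords + sum(b[j] * model.Ps[:, j]
                                  for j in range(model.n_modes))
    assert np.allclose(A.shape_from_params(model, b).coords, naive, atol=1e-10)
    with pytest.raises(ValueError):
        A.shape_from_params(model, np.zeros(model.n_modes + 1))


# ---------------------------------------------------------------------------
# pose transforms

def test_identity_pose_is_identity():
    s = _shape(TRIANGLE)
    out = A.apply_pose(s, A.PoseParams())
    assert np.allclose(out.points(), TRIANGLE)
    assert out.frame == IMAGE_FRAME


def test_quarter_turn():
    pose = A.PoseParams(-1.0, 1.0, 0.0, 0.0)   # s=1, theta=90 deg
    out = A.apply_pose(_shape([[1.0, 0.0]]), pose)
    assert np.allclose(out.points(), [[0.0, 1.0]], atol=1e-12)


def test_invert_pure_translation():
    inv = A.invert_pose(A.PoseParams(0, 0, 3, -2))
    assert np.allclose(inv.as_vector(), [0, 0, -3, 2])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.tuples(*[st.floats(-0.8, 0.8) for _ in range(2)],
                 *[st.floats(-50, 50) for _ in range(2)]))
def test_pose_roundtrip(vec):
    pose = A.PoseParams(*vec)
    inv = A.invert_pose(pose)
    pts = np.array([[0.3, -1.2], [4.0, 2.0], [-1.0, 0.5]])
    back = transform_points(transform_points(pts, pose), inv)
    assert np.allclose(back, pts, atol=1e-9)


def test_composition_with_inverse_is_identity(rng):
    pose = A.PoseParams(0.4, -0.3, 5.0, 2.0)
    comp = compose_pose(A.invert_pose(pose), pose)
    pts = rng.normal(size=(10, 2))
    assert np.allclose(transform_points(pts, comp), pts, atol=1e-9)


def test_pose_composition_closed_and_associative(rng):
    poses = [A.PoseParams(*rng.uniform(-0.5, 0.5, 2), *rng.uniform(-5, 5, 2))
             for _ in range(10)]
    pts = rng.normal(size=(7, 2))
    for p1, p2, p3 in zip(poses, poses[1:], poses[2:]):
        left = compose_pose(compose_pose(p3, p2), p1)
        right = compose_pose(p3, compose_pose(p2, p1))
        assert np.allclose(left.as_vector(), right.as_vector(), atol=1e-9)
        # closure: composite acts as applying both in sequence
        via = transform_points(transform_points(pts, p1), p2)
        assert np.allclose(transform_points(pts, compose_pose(p2, p1)), via,
                           atol=1e-9)


def test_degenerate_pose_not_invertible():
    with pytest.raises(ValueError):
        A.invert_pose(A.PoseParams(-1.0, 0.0, 0.0, 0.0))


def test_estimate_pose_recovers_transform(rng):
    pose = A.PoseParams(0.25, -0.4, 3.0, -7.0)
    src = _shape(TRIANGLE)
    dst = A.apply_pose(src, pose)
    est = A.estimate_pose(src, dst)
    assert np.allclose(est.as_vector(), pose.as_vector(), atol=1e-9)
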