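"""Triangulation, patch map, warping/sampling, normalization and texture PCA."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

import aamfit as A
from aamfit.shape import MODEL_FRAME, IMAGE_FRAME, LandmarkShape
from aamfit.texture import _rasterize, warp_positions


def _mshape(pts):
    return LandmarkShape.from_points(np.asarray(pts, dtype=float), MODEL_FRAME)


# ---------------------------------------------------------------------------
# triangulation

def test_three_points_one_triangle():
    tri = A.triangulate_mean_shape(_mshape([[0, 0], [1, 0], [0, 1]]))
    assert tri.shape == (1, 3)


def test_convex_quad_two_triangles():
    tri = A.triangulate_mean_shape(_mshape([[0, 0], [1, 0], [1, 1], [0, 1]]))
    assert tri.shape == (2, 3)


def test_triangle_count_follows_euler_formula(rng):
    pts = rng.normal(size=(20, 2))
    tri = A.triangulate_mean_shape(_mshape(pts))
    hull = ConvexHull(pts)
    assert len(tri) == 2 * 20 - 2 - len(hull.vertices)


def test_collinear_points_error():
    pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
    with pytest.raises(ValueError):
        A.triangulate_mean_shape(_mshape(pts))


# ---------------------------------------------------------------------------
# barycentric rasterization / patch map

def test_barycentric_at_vertex_and_centroid():
    pts = np.array([[0.0, 0.0], [30.0, 0.0], [0.0, 30.0]])
    tris = np.array([[0, 1, 2]])
    rows, cols, tri_idx, bary = _rasterize(pts, tris, 40, 40)
    lut = {(r, c): b for r, c, b in zip(rows, cols, bary)}
    assert np.allclose(sorted(lut[(0, 0)]), [0, 0, 1], atol=1e-12)
    assert np.allclose(lut[(10, 10)], [1 / 3, 1 / 3, 1 / 3], atol=1e-9)


@pytest.mark.parametrize("target", [64, 1024, 4096])
def test_patch_map_hits_target_within_ten_percent(small_gen, target):
    pmap = A.build_patch_map(small_gen.mean_shape, small_gen.triangles, target)
    assert abs(pmap.pixel_count - target) <= 0.10 * target


def test_patch_map_partition_of_unity_and_position(small_gen):
    pmap = small_gen.patch_map
    assert np.allclose(pmap.bary.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(pmap.bary >= -1e-9) and np.all(pmap.bary <= 1 + 1e-9)
    assert np.all(pmap.tri_index >= 0)
    assert np.all(pmap.tri_index < len(pmap.triangles))
    # barycentric combination reproduces each pixel center
    pos = np.einsum("pk,pkc->pc", pmap.bary,
                    pmap.patch_points[pmap.triangles[pmap.tri_index]])
    assert np.allclose(pos[:, 0], pmap.cols, atol=1e-9)
    assert np.allclose(pos[:, 1], pmap.rows, atol=1e-9)


def test_patch_map_minimum_size_guard(small_gen):
    with pytest.raises(ValueError):
        A.build_patch_map(small_gen.mean_shape, small_gen.triangles, 32)


# ---------------------------------------------------------------------------
# bilinear interpolation & sampling

def test_bilinear_exact_at_integer_coordinates(rng):
    img = rng.normal(size=(8, 9))
    ys, xs = np.mgrid[0:8, 0:9]
    vals = A.bilinear_sample(img, xs.ravel().astype(float),
                             ys.ravel().astype(float))
    assert np.array_equal(vals.reshape(8, 9), img)


def test_bilinear_exact_on_affine_images(rng):
    ys, xs = np.mgrid[0:20, 0:30]
    img = 0.7 * xs + 0.2 * ys + 3.0
    x = rng.uniform(0, 29, 100)
    y = rng.uniform(0, 19, 100)
    assert np.allclose(A.bilinear_sample(img, x, y), 0.7 * x + 0.2 * y + 3.0,
                       atol=1e-9)


def test_bilinear_clamps_at_border():
    img = np.arange(12.0).reshape(3, 4)
    assert A.bilinear_sample(img, np.array([-5.0]), np.array([0.0]))[0] == 0.0
    assert A.bilinear_sample(img, np.array([99.0]), np.array([99.0]))[0] == 11.0


def test_constant_image_samples_constant(small_gen):
    pmap = small_gen.patch_map
    S = A.apply_pose(small_gen.mean_shape, small_gen.canonical_pose())
    img = np.full(small_gen.image_shape(), 7.0)
    g = A.sample_texture(img, S, pmap)
    assert np.allclose(g.values, 7.0)


def test_ramp_image_sampling_matches_warp_positions(small_gen):
    pmap = small_gen.patch_map
    S = A.apply_pose(small_gen.mean_shape, small_gen.canonical_pose())
    h, w = small_gen.image_shape()
    img = np.tile(np.arange(w, dtype=float), (h, 1))   # I(x, y) = x
    g = A.sample_texture(img, S, pmap)
    pos = warp_positions(S.points(), pmap)
    assert np.allclose(g.values, pos[:, 0], atol=1e-6)


def test_identity_warp_recovers_mean_patch(small_gen):
    img, lm = A.render_instance(small_gen, noise_sigma=0.0)
    g = A.sample_texture(img, lm, small_gen.patch_map)
    pix = np.column_stack([small_gen.patch_map.cols,
                           small_gen.patch_map.rows]).astype(float)
    assert np.allclose(g.values, small_gen.mean_field(pix), atol=1e-6)


def test_warp_self_consistency_at_rotated_pose(small_gen):
    """Sampling the patch rendered at an arbitrary pose recovers the patch.

    Pixels near the patch boundary are excluded: their bilinear support in
    the rendered image reaches background pixels.  The tolerance is twice
    the bilinear curvature bound max|f''| h^2 / 8 of the cosine mixture.
    """
    from scipy.ndimage import binary_erosion

    base = small_gen.canonical_pose()
    s, th = base.scale_theta()
    pose = A.PoseParams.from_similarity(s, th + 0.15, base.t_x + 0.6,
                                        base.t_y - 0.4)
    img, lm = A.render_instance(small_gen, pose=pose, noise_sigma=0.0,
                                image_shape=tuple(int(1.8 * x) for x in
                                                  small_gen.image_shape()))
    g = A.sample_texture(img, lm, small_gen.patch_map)
    pmap = small_gen.patch_map
    pix = np.column_stack([pmap.cols, pmap.rows]).astype(float)

    inside = np.zeros((pmap.height, pmap.width), dtype=bool)
    inside[pmap.rows, pmap.cols] = True
    interior = binary_erosion(inside, iterations=3)[pmap.rows, pmap.cols]
    assert interior.sum() > 0.5 * pmap.pixel_count

    omega2 = np.sum(small_gen.field_freq**2, axis=1)
    tol = 2.0 * np.sum(np.abs(small_gen.mean_coefs) * omega2) / 8.0
    err = np.abs(g.values - small_gen.mean_field(pix))
    assert np.max(err[interior]) < tol


def test_sample_rejects_nan_image(small_gen):
    S = A.apply_pose(small_gen.mean_shape, small_gen.canonical_pose())
    img = np.full(small_gen.image_shape(), np.nan)
    with pytest.raises(ValueError):
        A.sample_texture(img, S, small_gen.patch_map)


# ---------------------------------------------------------------------------
# photometric normalization

def _g0(n=200, seed=0):
    return A.standardize_texture(np.random.default_rng(seed).normal(size=n))


def test_normalize_mean_is_fixed_point():
    g0 = _g0()
    g, params = A.normalize_texture(g0, g0)
    assert np.isclose(params.alpha_p, 1.0) and np.isclose(params.beta_p, 0.0)
    assert np.allclose(g.values, g0)


def test_normalize_recovers_scale_and_offset():
    g0 = _g0()
    g, params = A.normalize_texture(3.0 * g0 + 5.0, g0)
    assert np.isclose(params.alpha_p, 3.0) and np.isclose(params.beta_p, 5.0)
    assert np.allclose(g.values, g0, atol=1e-10)


def test_normalize_matches_least_squares_oracle(rng):
    g0 = _g0()
    g_im = rng.normal(size=g0.size)
    g, params = A.normalize_texture(g_im, g0)
    # oracle: fit g_im ~ alpha*g0 + beta*1 by generic least squares
    design = np.column_stack([g0, np.ones_like(g0)])
    (alpha, beta), *_ = np.linalg.lstsq(design, g_im, rcond=None)
    assert np.isclose(params.alpha_p, alpha, atol=1e-8)
    assert np.isclose(params.beta_p, beta, atol=1e-8)
    assert abs(g.values.sum()) < 1e-8
    assert np.isclose(g.values @ g0, g0 @ g0, atol=1e-6)


def test_normalize_idempotent(rng):
    g0 = _g0()
    g1, _ = A.normalize_texture(rng.normal(size=g0.size), g0)
    g2, _ = A.normalize_texture(g1.values, g0)
    assert np.allclose(g1.values, g2.values, atol=1e-9)


def test_normalize_orthogonal_texture_error():
    g0 = A.standardize_texture(np.array([1.0, -1.0, 1.0, -1.0]))
    with pytest.raises(ValueError):
        A.normalize_texture(np.array([1.0, 1.0, -1.0, -1.0]), g0)


# ---------------------------------------------------------------------------
# mean normalized texture (fixed point)

def test_mean_of_identical_samples():
    v = np.random.default_rng(3).normal(size=100)
    mean = A.compute_mean_normalized_texture([v, v, v])
    assert np.allclose(mean.values, A.standardize_texture(v), atol=1e-12)


def test_mean_of_affine_family():
    g = np.random.default_rng(4).normal(size=100)
    samples = [a * g + b for a, b in [(1.0, 0.0), (2.5, 1.0), (0.5, -3.0)]]
    mean = A.compute_mean_normalized_texture(samples)
    assert np.allclose(mean.values, A.standardize_texture(g), atol=1e-8)


def test_mean_is_fixed_point(rng):
    base = rng.normal(size=150)
    samples = [2.0 * base + rng.normal(0, 0.3, 150) for _ in range(10)]
    mean = A.compute_mean_normalized_texture(samples)
    renorm = [A.normalize_texture(s, mean)[0].values for s in samples]
    again = A.standardize_texture(np.mean(renorm, axis=0))
    assert np.allclose(again, mean.values, atol=1e-6)


# ---------------------------------------------------------------------------
# texture PCA

def test_texture_pca_identical_samples():
    v = A.standardize_texture(np.random.default_rng(5).normal(size=60))
    model = A.build_texture_pca([v, v, v], 0.98)
    assert model.n_modes == 0


def test_texture_pca_rank_one(rng):
    g0 = _g0(80)
    d = rng.normal(size=80)
    d /= np.linalg.norm(d)
    model = A.build_texture_pca([g0 + t * d for t in (-1, 0, 1)], 1.0)
    assert model.n_modes == 1
    assert np.isclose(abs(model.Pg[:, 0] @ d), 1.0, atol=1e-8)


def test_texture_pca_eigenvalues_match_oracle(rng):
    g0 = _g0(100)
    modes = np.linalg.qr(rng.normal(size=(100, 2)))[0]
    samples = [g0 + modes @ rng.normal(0, [1.5, 0.4]) for _ in range(25)]
    model = A.build_texture_pca(samples, 1.0)
    ev = np.linalg.eigvalsh(np.cov(np.stack(samples).T))[::-1]
    assert np.allclose(model.eigenvalues, ev[:model.n_modes], atol=1e-6)
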