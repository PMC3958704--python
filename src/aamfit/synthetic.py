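"""Synthetic landmarked images with known shape/texture/pose ground truth.

The generator emulates the face-model regime the package targets — tens of
landmarks (68 by default: an elliptical outline plus eye/nose/mouth
clusters), ~10^2 Delaunay triangles, patch textures from 4096 to 65536
pixels — without requiring any dataset.  Shapes deform along orthonormal
smooth (low-order polynomial) displacement modes; textures are band-limited
2-D cosine mixtures, so bilinear interpolation error stays far below the
recovery tolerances the tests assert.

Rendering inverts the sampling pipeline: the continuous texture is evaluated
at the piecewise-affine preimage of every image pixel inside the posed
triangulation, then the photometric transform and optional Gaussian noise
are applied.  At the canonical pose (integer patch-to-image offset) the
round trip render -> sample is exact to rounding, which anchors the
self-consistency tests.

Everything is deterministic given ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import appearance
from .appearance import CombinedModel
from .model import AAMModel
from .shape import (IMAGE_FRAME, MODEL_FRAME, LandmarkShape, PoseParams,
                    ShapePCAModel, transform_points)
from .texture import (PatchMap, TexturePCAModel, TextureVector, _rasterize,
                      build_patch_map, standardize_texture,
                      triangulate_mean_shape)


@dataclass
class SyntheticSpec:
    """Study conditions of the synthetic regime.

    Amplitudes are per-mode coefficient standard deviations: shape modes are
    unit vectors in the (unit-norm) model frame, texture modes have unit
    per-pixel RMS, so ``texture_amplitude`` is directly an intensity
    standard deviation and ``shape_amplitude`` 0.08 corresponds to roughly
    two pixels of landmark scatter at the default 4096-pixel patch.
    ``noise_sigma`` 0.01 is ~1% of the intensity range (mild sensor noise).
    The mean texture field has element std ~0.12, several times the default
    per-example texture variation, mirroring how a mean face dominates
    identity variation; the photometric fixed point that defines the mean
    normalized texture needs this dominance to be well-posed.
    """

    n_landmarks: int = 68
    target_pixels: int = 4096
    n_shape_modes: int = 3
    n_texture_modes: int = 4
    shape_amplitude: float = 0.08
    texture_amplitude: float = 0.04
    noise_sigma: float = 0.01
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_landmarks, self.target_pixels) <= 0:
            raise ValueError("counts must be positive")
        if self.n_shape_modes < 0 or self.n_texture_modes < 0:
            raise ValueError("mode counts must be nonnegative")
        if min(self.shape_amplitude, self.texture_amplitude,
               self.noise_sigma) < 0:
            raise ValueError("amplitudes must be nonnegative")


def _face_layout(n: int) -> np.ndarray:
    """Face-like landmark layout: elliptical outline + interior clusters."""
    if n < 16:
        # small test shapes: outline only
        th = 2 * np.pi * np.arange(n) / n
        return np.column_stack([np.cos(th), 1.3 * np.sin(th)])
    n_eye = max(3, n // 10)
    n_mouth = max(4, n // 7)
    n_nose = max(2, n // 12)
    n_out = n - 2 * n_eye - n_mouth - n_nose
    th = 2 * np.pi * np.arange(n_out) / n_out
    outline = np.column_stack([np.cos(th), 1.3 * np.sin(th)])
    clusters = [outline]
    for cx in (-0.38, 0.38):
        te = 2 * np.pi * np.arange(n_eye) / n_eye
        clusters.append(np.column_stack([cx + 0.16 * np.cos(te),
                                         -0.45 + 0.10 * np.sin(te)]))
    tm = 2 * np.pi * np.arange(n_mouth) / n_mouth
    clusters.append(np.column_stack([0.30 * np.cos(tm),
                                     0.55 + 0.15 * np.sin(tm)]))
    tn = np.arange(n_nose)
    clusters.append(np.column_stack([0.04 * np.sin(2.0 + tn),
                                     np.linspace(-0.15, 0.25, n_nose)]))
    return np.vstack(clusters)


def _similarity_basis(points: np.ndarray) -> np.ndarray:
    """Translation/scale/rotation directions at a centered shape (model layout)."""
    n = points.shape[0]
    x, y = points[:, 0], points[:, 1]
    zeros, ones = np.zeros(n), np.ones(n)
    return np.column_stack([
        np.concatenate([ones, zeros]),    # t_x
        np.concatenate([zeros, ones]),    # t_y
        np.concatenate([x, y]),           # scale
        np.concatenate([-y, x]),          # rotation
    ])


def make_shape_family(spec: SyntheticSpec, rng: np.random.Generator | None = None):
    """Mean shape (model frame) plus orthonormal smooth deformation modes.

    Modes are random low-order polynomial displacement fields evaluated at
    the landmarks, with the four similarity directions projected out so pose
    and shape do not confound, then orthonormalized.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    pts = _face_layout(spec.n_landmarks)
    pts = pts - pts.mean(axis=0)
    pts = pts / np.linalg.norm(pts)
    mean = LandmarkShape.from_points(pts, MODEL_FRAME)

    k = spec.n_shape_modes
    if k == 0:
        return mean, np.zeros((2 * spec.n_landmarks, 0))
    x, y = pts[:, 0], pts[:, 1]
    # polynomial displacement basis of degree 1..3 (no constant term)
    basis = np.column_stack([x, y, x * x, x * y, y * y,
                             x**3, x * x * y, x * y * y, y**3])
    raw = np.empty((2 * spec.n_landmarks, k + 2))
    for j in range(k + 2):
        cx = rng.normal(size=basis.shape[1])
        cy = rng.normal(size=basis.shape[1])
        raw[:, j] = np.concatenate([basis @ cx, basis @ cy])
    full = np.column_stack([_similarity_basis(pts), raw])
    q, _ = np.linalg.qr(full)
    modes = q[:, 4:4 + k]
    for j in range(modes.shape[1]):   # reproducible sign
        nz = np.flatnonzero(np.abs(modes[:, j]) > 1e-12)
        if nz.size and modes[nz[0], j] < 0:
            modes[:, j] = -modes[:, j]
    return mean, np.ascontiguousarray(modes)


@dataclass
class SyntheticGenerator:
    """Bundled ground-truth model behind a batch of rendered images."""

    spec: SyntheticSpec
    mean_shape: LandmarkShape
    shape_modes: np.ndarray          # (2n, k_s) orthonormal
    triangles: np.ndarray
    patch_map: PatchMap
    # continuous texture machinery: value(u) = base + fields(u) @ coefs
    field_freq: np.ndarray           # (m, 2) wave vectors, patch frame
    field_phase: np.ndarray          # (m,)
    mean_coefs: np.ndarray           # (m,) coefficients of the mean field
    mode_coefs: np.ndarray           # (m + 2, k_t): columns over [1, f0, fields]
    pad: int = 8

    # -- continuous texture -------------------------------------------------
    def _raw_fields(self, pts: np.ndarray) -> np.ndarray:
        phase = pts @ self.field_freq.T + self.field_phase
        return np.cos(phase)

    def mean_field(self, pts: np.ndarray) -> np.ndarray:
        return 0.5 + self._raw_fields(pts) @ self.mean_coefs

    def texture_at(self, pts: np.ndarray, b_g) -> np.ndarray:
        """Continuous texture value at patch-frame positions."""
        f0 = self.mean_field(pts)
        b_g = np.asarray(b_g, dtype=np.float64).ravel()
        if b_g.size == 0:
            return f0
        B = np.column_stack([np.ones(len(pts)), f0, self._raw_fields(pts)])
        return f0 + (B @ self.mode_coefs) @ b_g

    # -- geometry helpers ---------------------------------------------------
    @property
    def n_texture_modes(self) -> int:
        return self.mode_coefs.shape[1]

    def image_shape(self) -> tuple[int, int]:
        return (self.patch_map.height + 2 * self.pad,
                self.patch_map.width + 2 * self.pad)

    def canonical_pose(self) -> PoseParams:
        """Pure-scaling pose placing patch pixels on integer image coordinates."""
        return PoseParams(self.patch_map.scale - 1.0, 0.0,
                          float(self.patch_map.offset[0] + self.pad),
                          float(self.patch_map.offset[1] + self.pad))

    def shape_points(self, b_s) -> np.ndarray:
        b_s = np.asarray(b_s, dtype=np.float64).ravel()
        coords = self.mean_shape.coords + self.shape_modes @ b_s
        n = self.mean_shape.n_points
        return np.column_stack([coords[:n], coords[n:]])


def make_generator(spec: SyntheticSpec) -> SyntheticGenerator:
    rng = np.random.default_rng(spec.rng_seed)
    mean, modes = make_shape_family(spec, rng)
    triangles = triangulate_mean_shape(mean)
    pmap = build_patch_map(mean, triangles, spec.target_pixels)

    # Band-limited cosine fields.  The mean field mixes wavelengths from
    # ~10 px up to the patch width with roughly 1/f amplitudes: the
    # mid-frequency content plays the role of facial detail (edges), which
    # is what localizes alignment; the per-example modes stay low-frequency
    # (identity variation is smooth).
    width = max(pmap.width, pmap.height)
    m_mean, m_modes = 14, spec.n_texture_modes + 6
    m = m_mean + m_modes
    wl_mean = np.exp(rng.uniform(np.log(10.0), np.log(1.2 * width), size=m_mean))
    wl_modes = rng.uniform(0.5, 1.5, size=m_modes) * width
    wavelengths = np.concatenate([wl_mean, wl_modes])
    angles = rng.uniform(0, 2 * np.pi, size=m)
    freq = (2 * np.pi / wavelengths)[:, None] * np.column_stack(
        [np.cos(angles), np.sin(angles)])
    phase = rng.uniform(0, 2 * np.pi, size=m)
    amp = np.zeros(m)
    amp[:m_mean] = rng.uniform(0.5, 1.0, size=m_mean) * (wl_mean / wl_mean.max()) ** 0.5
    # element std of the mean field ~ 0.13 so the shared texture dominates the
    # per-example modes, as a mean face dominates identity variation
    mean_coefs = 0.13 * np.sqrt(2.0) * amp / np.linalg.norm(amp)

    gen = SyntheticGenerator(spec=spec, mean_shape=mean, shape_modes=modes,
                             triangles=triangles, patch_map=pmap,
                             field_freq=freq, field_phase=phase,
                             mean_coefs=mean_coefs,
                             mode_coefs=np.zeros((m + 2, 0)))
    if spec.n_texture_modes:
        pix = np.column_stack([pmap.cols, pmap.rows]).astype(np.float64)
        f0 = gen.mean_field(pix)
        raw = gen._raw_fields(pix)
        B = np.column_stack([np.ones(len(pix)), f0, raw[:, m_mean:]])
        _, r = np.linalg.qr(B)
        # columns 2.. are orthogonal to span{1, f0} = span{1, g0}
        C = np.linalg.solve(r, np.eye(r.shape[0]))[:, 2:2 + spec.n_texture_modes]
        C *= np.sqrt(len(pix))       # unit per-pixel RMS
        full = np.zeros((m + 2, spec.n_texture_modes))
        full[:2] = C[:2]
        full[2 + m_mean:] = C[2:]
        gen.mode_coefs = full
    return gen


def render_instance(gen: SyntheticGenerator, b_s=None, b_g=None,
                    pose: PoseParams | None = None, photo=(1.0, 0.0),
                    noise_sigma: float | None = None,
                    rng: np.random.Generator | None = None,
                    image_shape: tuple[int, int] | None = None):
    """Render one image; returns ``(image, landmarks)`` with exact ground truth."""
    ks = gen.shape_modes.shape[1]
    b_s = np.zeros(ks) if b_s is None else np.asarray(b_s, dtype=np.float64)
    b_g = (np.zeros(gen.n_texture_modes) if b_g is None
           else np.asarray(b_g, dtype=np.float64))
    pose = pose or gen.canonical_pose()
    alpha_p, beta_p = float(photo[0]), float(photo[1])
    h, w = image_shape or gen.image_shape()

    pts_img = transform_points(gen.shape_points(b_s), pose)
    image = np.full((h, w), alpha_p * 0.5 + beta_p)
    rows, cols, tri_idx, bary = _rasterize(pts_img, gen.triangles, h, w)
    if rows.size:
        patch_pos = np.einsum(
            "pk,pkc->pc", bary,
            gen.patch_map.patch_points[gen.triangles[tri_idx]])
        image[rows, cols] = alpha_p * gen.texture_at(patch_pos, b_g) + beta_p

    sigma = gen.spec.noise_sigma if noise_sigma is None else noise_sigma
    if sigma > 0:
        rng = rng if rng is not None else np.random.default_rng(gen.spec.rng_seed)
        image = image + rng.normal(0.0, sigma, size=image.shape)
    return image, LandmarkShape.from_points(pts_img, IMAGE_FRAME)


def make_sequence(gen: SyntheticGenerator, trajectory, noise_sigma=None,
                  rng: np.random.Generator | None = None):
    """Render a frame sequence from per-frame (b_s, b_g, pose) parameters."""
    trajectory = list(trajectory)
    if not trajectory:
        raise ValueError("trajectory must contain at least one frame")
    frames = []
    for b_s, b_g, pose in trajectory:
        frames.append(render_instance(gen, b_s, b_g, pose,
                                      noise_sigma=noise_sigma, rng=rng))
    return frames


def drift_trajectory(gen: SyntheticGenerator, n_frames: int,
                     drift: tuple[float, float] = (0.5, 0.0), b_s=None, b_g=None):
    """Linear pose drift of ``drift`` pixels per frame from the canonical pose."""
    base = gen.canonical_pose()
    out = []
    for i in range(n_frames):
        pose = PoseParams(base.s_x, base.s_y,
                          base.t_x + i * drift[0], base.t_y + i * drift[1])
        out.append((b_s, b_g, pose))
    return out


def make_training_set(gen: SyntheticGenerator, n: int,
                      rng: np.random.Generator | None = None,
                      pose_jitter: bool = True, photo_jitter: bool = True):
    """Random instances for model training; returns (images, landmarks, truth).

    ``truth`` rows are dicts with the generating b_s, b_g, pose and photo.
    """
    rng = rng if rng is not None else np.random.default_rng(gen.spec.rng_seed + 1)
    spec = gen.spec
    ks, kt = gen.shape_modes.shape[1], gen.n_texture_modes
    base = gen.canonical_pose()
    images, landmarks, truth = [], [], []
    for _ in range(n):
        b_s = rng.normal(0, spec.shape_amplitude, size=ks)
        b_g = rng.normal(0, spec.texture_amplitude, size=kt)
        pose = base
        if pose_jitter:
            s, th = base.scale_theta()
            pose = PoseParams.from_similarity(
                s * (1 + rng.uniform(-0.03, 0.03)),
                th + rng.uniform(-0.05, 0.05),
                base.t_x + rng.uniform(-2, 2), base.t_y + rng.uniform(-2, 2))
        photo = (1.0, 0.0)
        if photo_jitter:
            photo = (rng.uniform(0.9, 1.1), rng.uniform(-0.05, 0.05))
        img, lm = render_instance(gen, b_s, b_g, pose, photo, rng=rng)
        images.append(img)
        landmarks.append(lm)
        truth.append({"b_s": b_s, "b_g": b_g, "pose": pose, "photo": photo})
    return images, landmarks, truth


def as_aam_model(gen: SyntheticGenerator) -> AAMModel:
    """Wrap the generator's exact bases as a trained appearance model.

    The generator *is* a linear shape/texture model, so its modes can serve
    directly as a model container (no gradient matrix): shape modes become
    Ps, the standardized mean field becomes g0, and the texture modes
    (rescaled to orthonormal columns) become Pg.  Useful for tests that need
    a model with known ground truth but no training run.
    """
    spec = gen.spec
    pix = np.column_stack([gen.patch_map.cols, gen.patch_map.rows]).astype(np.float64)
    f0 = gen.mean_field(pix)
    sigma0 = float(np.std(f0))
    g0 = standardize_texture(f0)
    npix = len(pix)
    kt = gen.n_texture_modes
    if kt:
        B = np.column_stack([np.ones(npix), f0, gen._raw_fields(pix)])
        M = B @ gen.mode_coefs                 # unit per-pixel RMS, zero-sum, _|_ g0
        Pg = M / np.sqrt(npix)
    else:
        Pg = np.zeros((npix, 0))
    ks = gen.shape_modes.shape[1]
    lam_s = np.full(ks, spec.shape_amplitude**2)
    lam_g = np.full(kt, (spec.texture_amplitude * np.sqrt(npix) / sigma0) ** 2)

    shape_model = ShapePCAModel(s0=gen.mean_shape, Ps=gen.shape_modes,
                                eigenvalues=lam_s,
                                total_variance=float(lam_s.sum()))
    texture_model = TexturePCAModel(g0=TextureVector(g0, normalized=True),
                                    Pg=Pg, eigenvalues=lam_g,
                                    total_variance=float(lam_g.sum()))
    w = appearance.default_shape_weight(shape_model, texture_model)
    lam = np.concatenate([w * w * lam_s, lam_g])
    order = np.argsort(-lam, kind="stable")
    eye = np.eye(ks + kt)[:, order]
    combined = CombinedModel(
        shape=shape_model, texture=texture_model,
        Qs=np.hstack([shape_model.Ps / w, np.zeros((2 * gen.mean_shape.n_points, kt))])[:, order],
        Qg=np.hstack([np.zeros((npix, ks)), Pg])[:, order],
        Pc_shape=eye[:ks], Pc_texture=eye[ks:],
        shape_weight=w, eigenvalues=lam[order])
    return AAMModel(combined=combined, patch_map=gen.patch_map,
                    meta={"synthetic": True, "sigma0": sigma0,
                          "target_pixels": spec.target_pixels,
                          "seed": spec.rng_seed})


def true_appearance_params(gen: SyntheticGenerator, model: AAMModel,
                           b_s, b_g) -> np.ndarray:
    """Appearance vector c of ``model`` reproducing a generator instance."""
    sigma0 = model.meta["sigma0"]
    npix = model.n_pixels
    b_s = np.asarray(b_s, dtype=np.float64).ravel()
    b_g_model = np.asarray(b_g, dtype=np.float64).ravel() * np.sqrt(npix) / sigma0
    return appearance.project_params(model.combined, b_s, b_g_model)
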