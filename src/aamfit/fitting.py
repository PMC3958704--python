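"""Iterative appearance-model search and frame-to-frame tracking.

One fitting iteration evaluates the texture residual between the image and
the model at the current parameters p = (c | t | u):

    r(p) = g_s - g_m,      E(p) = r^T r

where g_s is the image texture sampled under the posed model shape and
normalized into the texture frame, and g_m = g0 + Qg c is the model texture.
The parameter update is the precomputed linear regression

    dp = -R r(p)

with R estimated once from displacement experiments on the training set.  The
loop accepts the first step multiplier that lowers E and declares convergence
when none does.

By default the photometric parameters u are re-estimated analytically inside
the normalization at every residual evaluation (they then ride along in
``FitParams.photo`` for reporting); ``include_photo`` switches to carrying u
explicitly in p and updating it through R like the other parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import AAMModel
from .shape import (IMAGE_FRAME, LandmarkShape, PoseParams, transform_points)
from .texture import (PhotometricParams, TextureVector, normalize_texture,
                      sample_texture)

DEFAULT_STEPS = (1.0, 1.5, 0.5, 0.25)


@dataclass
class FitParams:
    """Current model state: appearance c, pose t, photometric u."""

    c: np.ndarray
    pose: PoseParams = field(default_factory=PoseParams)
    photo: PhotometricParams = field(default_factory=PhotometricParams)

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=np.float64).ravel()

    def copy(self) -> "FitParams":
        return FitParams(self.c.copy(), replace(self.pose), replace(self.photo))


@dataclass
class ResidualState:
    g_s: TextureVector
    g_m: TextureVector
    r: np.ndarray
    E: float
    photo: PhotometricParams | None = None


@dataclass
class PerturbationSpec:
    """Displacement ranges for the gradient-matrix regression experiments."""

    translation: float = 3.0      # pixels, uniform +/-
    scale: float = 0.05           # relative, uniform +/-
    rotation_deg: float = 5.0     # degrees, uniform +/-
    c_std: float = 0.5            # appearance, in per-mode standard deviations
    photo_scale: float = 0.05     # contrast, relative (include_photo only)
    photo_offset: float = 0.05    # brightness (include_photo only)

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in
                ("translation", "scale", "rotation_deg", "c_std",
                 "photo_scale", "photo_offset")}


@dataclass
class GradientMatrix:
    R: np.ndarray                      # (n_params, n_pixels)
    perturbation_spec: PerturbationSpec
    include_photo: bool = False

    @property
    def n_params(self) -> int:
        return self.R.shape[0]


def posed_shape(model: AAMModel, p: FitParams, image_shape,
                dtype=np.float64) -> LandmarkShape:
    """Model shape at c, posed into the image frame and clamped to the image."""
    c = p.c.astype(dtype, copy=False)
    s = model.s0.coords.astype(dtype, copy=False) + model.Qs.astype(dtype, copy=False) @ c
    n = model.n_points
    pts = np.column_stack([s[:n], s[n:]])
    a, b = 1.0 + p.pose.s_x, p.pose.s_y
    if a * a + b * b < 1e-12:
        raise ValueError("degenerate pose: (1+s_x)^2 + s_y^2 = 0")
    pts = transform_points(pts, p.pose).astype(dtype, copy=False)
    h, w = image_shape
    pts[:, 0] = np.clip(pts[:, 0], 0.0, w - 1.0)
    pts[:, 1] = np.clip(pts[:, 1], 0.0, h - 1.0)
    return LandmarkShape.from_points(pts, IMAGE_FRAME)


def compute_residual(image: np.ndarray, model: AAMModel, p: FitParams,
                     dtype=np.float64, include_photo: bool = False) -> ResidualState:
    """Residual r = g_s - g_m and error E = r^T r at parameters p.

    The five serial stages: posed shape; texture sampling; photometric
    normalization; model texture; residual and error.
    """
    img = np.asarray(image, dtype=dtype)
    S = posed_shape(model, p, img.shape, dtype)
    g_im = sample_texture(img, S, model.patch_map, dtype)
    g0 = model.g0.values.astype(dtype, copy=False)
    if include_photo:
        if abs(p.photo.alpha_p) < 1e-12:
            raise ValueError("photometric contrast alpha_p is zero")
        g_s = TextureVector((g_im.values - dtype(p.photo.beta_p)) / dtype(p.photo.alpha_p),
                            normalized=True)
        photo = replace(p.photo)
    else:
        g_s, photo = normalize_texture(g_im.values, g0)
        g_s = TextureVector(g_s.values.astype(dtype, copy=False), normalized=True)
    g_m = g0 + model.Qg.astype(dtype, copy=False) @ p.c.astype(dtype, copy=False)
    r = g_s.values - g_m
    return ResidualState(g_s=g_s, g_m=TextureVector(g_m, normalized=True),
                         r=r, E=float(r @ r), photo=photo)


def _perturb_pose(pose: PoseParams, rng: np.random.Generator,
                  spec: PerturbationSpec) -> PoseParams:
    s, th = pose.scale_theta()
    s2 = s * (1.0 + rng.uniform(-spec.scale, spec.scale))
    th2 = th + np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
    return PoseParams.from_similarity(
        s2, th2,
        pose.t_x + rng.uniform(-spec.translation, spec.translation),
        pose.t_y + rng.uniform(-spec.translation, spec.translation))


def estimate_R(model: AAMModel, training, spec: PerturbationSpec | None = None,
               seed: int = 0, experiments_per_image: int | None = None,
               include_photo: bool = False) -> GradientMatrix:
    """Gradient matrix by multivariate linear regression on displacement experiments.

    ``training`` is a list of (image, ground-truth FitParams).  Around each
    example, known displacements dp are drawn inside ``spec`` and the residual
    observed at the displaced parameters is recorded; R solves the
    least-squares regression predicting dp from r, so -R r is the corrective
    update.  Deterministic for a given seed.
    """
    spec = spec or PerturbationSpec()
    training = list(training)
    if not training:
        raise ValueError("estimate_R needs at least one training image")
    n_params = model.k_c + 4 + (2 if include_photo else 0)
    if experiments_per_image is None:
        experiments_per_image = max(6, int(np.ceil(3.0 * n_params / len(training))))
    total = experiments_per_image * len(training)
    if total < n_params:
        raise ValueError(
            f"{total} experiments cannot identify {n_params} parameters")

    c_sd = np.sqrt(np.maximum(model.combined.eigenvalues, 0.0))
    rng = np.random.default_rng(seed)
    D = np.empty((total, n_params))
    X = np.empty((total, model.n_pixels))
    row = 0
    for image, p_true in training:
        for _ in range(experiments_per_image):
            dc = rng.uniform(-spec.c_std, spec.c_std, size=model.k_c) * c_sd
            pose2 = _perturb_pose(p_true.pose, rng, spec)
            photo2 = p_true.photo
            dphoto = np.zeros(0)
            if include_photo:
                da = p_true.photo.alpha_p * rng.uniform(-spec.photo_scale,
                                                        spec.photo_scale)
                db = rng.uniform(-spec.photo_offset, spec.photo_offset)
                photo2 = PhotometricParams(p_true.photo.alpha_p + da,
                                           p_true.photo.beta_p + db)
                dphoto = np.array([da, db])
            p2 = FitParams(c=p_true.c + dc, pose=pose2, photo=photo2)
            st = compute_residual(image, model, p2, include_photo=include_photo)
            D[row] = np.concatenate(
                [dc, pose2.as_vector() - p_true.pose.as_vector(), dphoto])
            X[row] = st.r
            row += 1
    # regress the residual on the displacement (overdetermined per pixel):
    # r ~ G dp, then invert the gradient so dp_hat = -R r with R = G^+.
    Gt, *_ = np.linalg.lstsq(D, X, rcond=None)      # (n_params, n_pixels) = G^T
    R = np.linalg.pinv(Gt.T)
    return GradientMatrix(R=np.ascontiguousarray(R), perturbation_spec=spec,
                          include_photo=include_photo)


def update_params(p: FitParams, r: np.ndarray, grad: GradientMatrix,
                  k: float = 1.0, matvec=None) -> FitParams:
    """Apply dp = -R r scaled by the step multiplier k."""
    mv = matvec if matvec is not None else (lambda R, v: R @ v)
    dp = -np.asarray(mv(grad.R, np.asarray(r, dtype=grad.R.dtype)), dtype=np.float64)
    kc = p.c.size
    out = p.copy()
    out.c = p.c + k * dp[:kc]
    out.pose = PoseParams.from_vector(p.pose.as_vector() + k * dp[kc:kc + 4])
    if grad.include_photo:
        out.photo = PhotometricParams(p.photo.alpha_p + k * dp[kc + 4],
                                      p.photo.beta_p + k * dp[kc + 5])
    return out


def fit(image: np.ndarray, model: AAMModel, p_init: FitParams,
        max_iter: int = 30, step_multipliers=DEFAULT_STEPS,
        fixed_iterations: bool = False, engine: str = "serial",
        cfg=None, dtype=np.float64, tol: float = 1e-10):
    """Iterative model search; returns (p, E, trace).

    Each iteration proposes dp = -R r and accepts the first step multiplier
    that lowers E by at least the relative ``tol`` (rounding-level
    fluctuations do not count as progress); the search stops when no
    multiplier improves E or after ``max_iter`` iterations.
    ``fixed_iterations=True`` follows the fixed per-frame iteration
    protocol: the trace always has ``max_iter`` entries (non-improving
    iterations leave the state unchanged).  ``engine`` selects the serial
    path or the deterministic data-parallel emulation.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if model.R is None:
        raise ValueError("model has no gradient matrix; run estimate_R first")
    grad = model.R

    if engine == "serial":
        residual = lambda pp: compute_residual(
            image, model, pp, dtype=dtype, include_photo=grad.include_photo)
        matvec = None
    elif engine == "parallel":
        from . import engine as eng
        cfg = cfg or eng.ExecConfig(dtype=dtype)
        residual = lambda pp: eng.par_compute_E(
            image, model, pp, cfg, include_photo=grad.include_photo)
        matvec = lambda R, v: eng.autotuned_matvec(R, v, cfg)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    p = p_init.copy()
    state = residual(p)
    if state.photo is not None and not grad.include_photo:
        p.photo = state.photo
    trace = [state.E]
    # E below the rounding noise of the residual sum counts as converged
    e_floor = model.n_pixels * (100.0 * np.finfo(np.dtype(dtype)).eps) ** 2
    for _ in range(max_iter):
        if state.E <= e_floor:
            if fixed_iterations:
                trace.extend([state.E] * (max_iter - len(trace) + 1))
            break
        cand_base = update_params(p, state.r, grad, 1.0, matvec)
        improved = False
        for k in step_multipliers:
            if k == 1.0:
                cand = cand_base
            else:
                cand = _scale_step(p, cand_base, k, grad)
            try:
                st2 = residual(cand)
            except ValueError:
                continue
            if st2.E < state.E * (1.0 - tol):
                p, state = cand, st2
                if state.photo is not None and not grad.include_photo:
                    p.photo = state.photo
                improved = True
                break
        trace.append(state.E)
        if not improved:
            if fixed_iterations:
                # remaining iterations are provably identical no-ops
                trace.extend([state.E] * (max_iter - len(trace) + 1))
            break
    return p, state.E, trace


def _scale_step(p: FitParams, p_unit: FitParams, k: float,
                grad: GradientMatrix) -> FitParams:
    """Rescale the unit step p -> p_unit by multiplier k."""
    out = p.copy()
    out.c = p.c + k * (p_unit.c - p.c)
    out.pose = PoseParams.from_vector(
        p.pose.as_vector() + k * (p_unit.pose.as_vector() - p.pose.as_vector()))
    if grad.include_photo:
        out.photo = PhotometricParams(
            p.photo.alpha_p + k * (p_unit.photo.alpha_p - p.photo.alpha_p),
            p.photo.beta_p + k * (p_unit.photo.beta_p - p.photo.beta_p))
    return out


def track(frames, model: AAMModel, p_init: FitParams, iterations: int = 10,
          engine: str = "serial", cfg=None, dtype=np.float64):
    """Fit a frame sequence; frame i > 1 starts from frame i-1's result.

    Uses a fixed number of iterations per frame (default 10, the standard
    per-frame evaluation protocol).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("track needs at least one frame")
    results = []
    p = p_init
    for frame in frames:
        p, E, _ = fit(frame, model, p, max_iter=iterations,
                      fixed_iterations=True, engine=engine, cfg=cfg, dtype=dtype)
        results.append((p.copy(), E))
    return results
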