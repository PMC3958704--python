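"""Deterministic emulation of the fine-grained data-parallel fitting hotspot.

The error computation E(p) decomposes into five data-parallel stages: posed
shape (one virtual thread per vertex), texture sampling (each thread handles
pixels i, i+N, i+2N, ... for N total threads), the four-phase texture
normalization separated by global barriers, the model texture, and the
residual/error stage.  Sums are computed by a three-level plan: thread-local
sequential accumulation, an in-block stride-halving tree over the block's
workspace (exactly log2(block_dim) combine rounds), and cross-block
accumulation in ascending block order.

This module reproduces the *numerics* of that decomposition — the combine
ordering, the virtual grid/block geometry, the single/double precision
switch — on the CPU, so results are bit-reproducible and can be checked
against the serial path.  Elementwise stages carry no cross-pixel
arithmetic, so they are evaluated as whole-lattice array operations through
the same kernels as the serial path (the thread mapping is then only a
labeling); all reductions follow the three-level order literally.  The
cross-block accumulation deliberately replaces a nondeterministically
ordered atomic add with a fixed ascending order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fitting import FitParams, ResidualState, posed_shape
from .model import AAMModel
from .shape import LandmarkShape
from .texture import PatchMap, PhotometricParams, TextureVector, _values, sample_texture


@dataclass(frozen=True)
class ExecConfig:
    """Virtual grid/block/thread lattice.

    The default 4 blocks x 1024 threads mirrors the configuration reported
    to saturate the reference hardware; here it only fixes the reduction
    ordering.  ``dtype`` is the global precision switch (float32 mirrors the
    single-precision reference arithmetic, float64 is the test default).
    """

    grid_dim: int = 4
    block_dim: int = 1024
    dtype: type = np.float64

    def __post_init__(self):
        if self.grid_dim < 1 or self.block_dim < 1:
            raise ValueError("grid_dim and block_dim must be positive")
        if self.block_dim & (self.block_dim - 1):
            raise ValueError("block_dim must be a power of two "
                             "(required by the halving reduction)")

    @property
    def n_threads(self) -> int:
        return self.grid_dim * self.block_dim


def three_level_sum(values, cfg: ExecConfig):
    """Sum by thread-local accumulation, in-block halving tree, cross-block order.

    Returns ``(total, combine_rounds)`` where ``combine_rounds`` counts the
    in-block tree iterations (always log2(block_dim)).
    """
    v = np.asarray(_values(values), dtype=cfg.dtype)
    N = cfg.n_threads
    pad = (-v.size) % N
    if pad:
        v = np.concatenate([v, np.zeros(pad, dtype=cfg.dtype)])
    # level 1: thread t accumulates v[t], v[t+N], ... sequentially
    acc = np.zeros(N, dtype=cfg.dtype)
    for k in range(v.size // N):
        acc += v[k * N:(k + 1) * N]
    # level 2: stride-halving tree within each block's workspace
    work = acc.reshape(cfg.grid_dim, cfg.block_dim).copy()
    rounds = 0
    stride = cfg.block_dim // 2
    while stride >= 1:
        work[:, :stride] += work[:, stride:2 * stride]
        rounds += 1
        stride //= 2
    # level 3: ascending block order (deterministic stand-in for atomicAdd)
    total = cfg.dtype(0.0)
    for b in range(cfg.grid_dim):
        total = total + work[b, 0]
    return total, rounds


def par_compute_shape(model: AAMModel, p: FitParams, cfg: ExecConfig,
                      image_shape) -> LandmarkShape:
    """Posed, image-clamped shape with one virtual thread per vertex."""
    if cfg.n_threads < model.n_points:
        raise ValueError(
            f"config provides {cfg.n_threads} threads for {model.n_points} vertices")
    return posed_shape(model, p, image_shape, dtype=cfg.dtype)


def par_sample_texture(image: np.ndarray, S: LandmarkShape, pmap: PatchMap,
                       cfg: ExecConfig) -> TextureVector:
    """Strided per-pixel piecewise-affine sampling.

    Pixel arithmetic is independent per pixel, so the strided thread mapping
    does not alter any operand; the result is bitwise identical to the serial
    sampler (they share one kernel).
    """
    return sample_texture(np.asarray(image, dtype=cfg.dtype), S, pmap,
                          dtype=cfg.dtype)


def par_normalize(g_s, g0, cfg: ExecConfig):
    """Four-phase texture normalization with barrier semantics.

    Phases (each completes over all data before the next): per-element mean;
    RMS norm of the centered texture (the texture is then centered and made
    unit-norm); per-element alignment product with the mean texture g0; final
    scaling.  Returns ``(g, stats)`` with stats = {mean, norm, alpha_dot};
    the result satisfies mean(g * g0) = 1 when alpha_dot > 0.
    """
    g = np.asarray(_values(g_s), dtype=cfg.dtype)
    g0v = np.asarray(_values(g0), dtype=cfg.dtype)
    if g.size != g0v.size:
        raise ValueError("texture length mismatch")
    n = cfg.dtype(g.size)

    s1, _ = three_level_sum(g, cfg)
    mean = s1 / n
    # --- barrier ---
    d = g - mean
    s2, _ = three_level_sum(d * d, cfg)
    norm = np.sqrt(s2 / n)
    if norm == 0:
        raise ValueError("degenerate (constant) texture")
    u = d / norm
    # --- barrier ---
    s3, _ = three_level_sum(u * g0v, cfg)
    alpha = s3 / n
    if abs(float(alpha)) < 1e-12:
        raise ValueError("texture is orthogonal to the mean (alpha_dot = 0)")
    # --- barrier ---
    out = u / alpha
    stats = {"mean": float(mean), "norm": float(norm), "alpha_dot": float(alpha)}
    return TextureVector(out, normalized=True), stats


def par_model_texture(model: AAMModel, c, cfg: ExecConfig) -> TextureVector:
    """g_m = g0 + Qg c, one row dot product per pixel (strided mapping)."""
    c = np.asarray(c, dtype=cfg.dtype).ravel()
    if c.size != model.k_c:
        raise ValueError(f"c has length {c.size}, model has {model.k_c} modes")
    g0 = model.g0.values.astype(cfg.dtype, copy=False)
    Qg = model.Qg.astype(cfg.dtype, copy=False)
    return TextureVector(g0 + Qg @ c, normalized=True)


def par_residual_error(g_s, g_m, cfg: ExecConfig):
    """Elementwise residual; error by three-level summation of squares."""
    a = np.asarray(_values(g_s), dtype=cfg.dtype)
    b = np.asarray(_values(g_m), dtype=cfg.dtype)
    if a.size != b.size:
        raise ValueError("texture length mismatch")
    r = a - b
    E, _ = three_level_sum(r * r, cfg)
    return r, float(E)


def autotuned_matvec(R: np.ndarray, r: np.ndarray, cfg: ExecConfig,
                     segment_target: int = 512) -> np.ndarray:
    """Wide matrix-vector product with an autotuned threads-per-row count.

    The number of threads cooperating on one output element is the smallest
    power of two whose per-thread segment is at most ``segment_target``
    columns, capped at the total thread count; each thread accumulates its
    strided column segment sequentially and the partials are combined by the
    deterministic halving tree.
    """
    R = np.asarray(R, dtype=cfg.dtype)
    r = np.asarray(r, dtype=cfg.dtype).ravel()
    if R.ndim != 2 or R.shape[1] != r.size:
        raise ValueError(f"dimension mismatch: R is {R.shape}, r has {r.size}")
    ncols = r.size
    T = 1
    while T * segment_target < ncols:
        T *= 2
    while T > cfg.n_threads and T > 1:
        T //= 2

    pad = (-ncols) % T
    if pad:
        R = np.concatenate([R, np.zeros((R.shape[0], pad), dtype=cfg.dtype)], axis=1)
        r = np.concatenate([r, np.zeros(pad, dtype=cfg.dtype)])
    partial = np.zeros((R.shape[0], T), dtype=cfg.dtype)
    for k in range(r.size // T):
        sl = slice(k * T, (k + 1) * T)
        partial += R[:, sl] * r[sl]
    stride = T // 2
    while stride >= 1:
        partial[:, :stride] += partial[:, stride:2 * stride]
        stride //= 2
    return partial[:, 0].copy()


def par_compute_E(image: np.ndarray, model: AAMModel, p: FitParams,
                  cfg: ExecConfig, include_photo: bool = False) -> ResidualState:
    """Composed parallel pipeline for the fitting hotspot E(p).

    The normalization stage produces the unit-alignment gauge
    (mean(g*g0) = 1); a final elementwise rescale by dot(g0, g0)/n — itself
    computed with the reduction plan — lands the texture in the model gauge,
    making the pipeline interchangeable with the serial residual.
    """
    img = np.asarray(image, dtype=cfg.dtype)
    S = par_compute_shape(model, p, cfg, img.shape)
    g_im = par_sample_texture(img, S, model.patch_map, cfg)
    g0 = model.g0.values.astype(cfg.dtype, copy=False)
    n = cfg.dtype(g0.size)
    if include_photo:
        if abs(p.photo.alpha_p) < 1e-12:
            raise ValueError("photometric contrast alpha_p is zero")
        g_s = TextureVector((g_im.values - cfg.dtype(p.photo.beta_p))
                            / cfg.dtype(p.photo.alpha_p), normalized=True)
        photo = replace(p.photo)
    else:
        g_unit, stats = par_normalize(g_im, g0, cfg)
        s_g0, _ = three_level_sum(g0 * g0, cfg)
        gauge = s_g0 / n     # = element variance of g0 (~1 by convention)
        g_s = TextureVector(g_unit.values * gauge, normalized=True)
        photo = PhotometricParams(
            alpha_p=float(stats["norm"] * stats["alpha_dot"] * n / s_g0),
            beta_p=stats["mean"])
    g_m = par_model_texture(model, p.c, cfg)
    r, E = par_residual_error(g_s, g_m, cfg)
    return ResidualState(g_s=g_s, g_m=g_m, r=r, E=E, photo=photo)
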