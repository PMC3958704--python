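"""Reproducible end-to-end experiments on synthetic data.

Each function runs one self-contained study — engine equivalence across
patch resolutions, reduction exactness, the autotuned mat-vec against a
naive oracle, parameter recovery, tracking under drift, and the
compute-cost scaling sweep across the 16-resolution regime — and returns
plain dictionaries of measured quantities.  They are the backing for both
the acceptance checks and the command-line sweep.
"""

from __future__ import annotations

import time

import numpy as np

from . import synthetic as syn
from .engine import ExecConfig, autotuned_matvec, par_compute_E, three_level_sum
from .fitting import FitParams, compute_residual, fit, posed_shape, track
from .model import train_aam

SWEEP_SIZES = tuple(4096 * i for i in range(1, 17))


def _perturbed_params(model, gen, rng):
    """Random parameters a plausible iteration away from a rendered truth."""
    spec = gen.spec
    b_s = rng.normal(0, spec.shape_amplitude, gen.shape_modes.shape[1])
    b_g = rng.normal(0, spec.texture_amplitude, gen.n_texture_modes)
    image, _ = syn.render_instance(gen, b_s, b_g, rng=rng)
    c = syn.true_appearance_params(gen, model, b_s, b_g)
    c = c + rng.normal(0, 0.2, c.size) * np.sqrt(
        np.maximum(model.combined.eigenvalues, 1e-12))
    pose = gen.canonical_pose()
    s, th = pose.scale_theta()
    from .shape import PoseParams
    pose = PoseParams.from_similarity(
        s * (1 + rng.uniform(-0.03, 0.03)), th + rng.uniform(-0.05, 0.05),
        pose.t_x + rng.uniform(-2, 2), pose.t_y + rng.uniform(-2, 2))
    return image, FitParams(c=c, pose=pose)


def engine_equivalence(seed: int = 0, n_trials: int = 100,
                       sizes=(4096, 16384, 65536),
                       cfg: ExecConfig | None = None) -> dict:
    """Serial vs. emulated-parallel E over random (model, image, p) triples.

    Returns the maximum relative |E_par - E_ser| / E_ser in double and in
    single precision.
    """
    rng = np.random.default_rng(seed)
    per = [n_trials // len(sizes)] * len(sizes)
    per[0] += n_trials - sum(per)
    worst = {"double": 0.0, "single": 0.0}
    for npx, count in zip(sizes, per):
        gen = syn.make_generator(syn.SyntheticSpec(
            target_pixels=npx, rng_seed=int(rng.integers(2**31))))
        model = syn.as_aam_model(gen)
        for _ in range(count):
            image, p = _perturbed_params(model, gen, rng)
            for name, dtype in (("double", np.float64), ("single", np.float32)):
                c = cfg or ExecConfig()
                c = ExecConfig(c.grid_dim, c.block_dim, dtype=dtype)
                E_s = compute_residual(image, model, p, dtype=dtype).E
                E_p = par_compute_E(image, model, p, c).E
                worst[name] = max(worst[name], abs(E_p - E_s) / E_s)
    return {"max_rel_err_double": worst["double"],
            "max_rel_err_single": worst["single"], "n": n_trials}


def reduction_exactness(k_range=range(5, 17),
                        cfgs=(ExecConfig(1, 32), ExecConfig(2, 256),
                              ExecConfig(4, 1024))) -> dict:
    """Three-level sums of all-ones vectors of length 2^k must be exact,
    with exactly log2(block_dim) in-block combine rounds."""
    max_err = 0.0
    round_deviation = 0
    n = 0
    for cfg in cfgs:
        for k in k_range:
            total, rounds = three_level_sum(np.ones(2**k), cfg)
            max_err = max(max_err, abs(float(total) - 2.0**k))
            round_deviation = max(round_deviation,
                                  abs(rounds - int(np.log2(cfg.block_dim))))
            n += 1
    return {"max_abs_error": max_err, "round_deviation": round_deviation,
            "n": n}


def matvec_agreement(seed: int = 0, n_matrices: int = 50,
                     cfg: ExecConfig | None = None) -> dict:
    """Autotuned mat-vec vs. a naive product over 10x100 .. 64x65536 shapes."""
    rng = np.random.default_rng(seed)
    cfg = cfg or ExecConfig()
    shapes = [(10, 100), (64, 65536)]
    while len(shapes) < n_matrices:
        rows = int(np.exp(rng.uniform(np.log(10), np.log(64))))
        cols = int(np.exp(rng.uniform(np.log(100), np.log(65536))))
        shapes.append((rows, cols))
    worst = 0.0
    for rows, cols in shapes:
        R = rng.normal(size=(rows, cols))
        r = rng.normal(size=cols)
        out = autotuned_matvec(R, r, cfg)
        ref = R @ r
        worst = max(worst, float(np.max(np.abs(out - ref))
                                 / np.max(np.abs(ref))))
    return {"max_rel_err": worst, "n": len(shapes)}


def _trained_face_model(seed: int, n_training: int = 30):
    gen = syn.make_generator(syn.SyntheticSpec(rng_seed=seed))
    images, landmarks, _ = syn.make_training_set(
        gen, n_training, np.random.default_rng(seed + 1))
    model = train_aam(images, landmarks, target_pixels=4096, seed=seed)
    return gen, model


def parameter_recovery(seed: int = 0, n_trials: int = 50) -> dict:
    """Fit held-out instances from inits inside the training perturbation range.

    Reports the median landmark error and the median/max translation
    (landmark centroid) error in pixels over the trials.
    """
    gen, model = _trained_face_model(seed)
    spec = gen.spec
    rng = np.random.default_rng(seed + 2)
    lm_errors, t_errors = [], []
    for _ in range(n_trials):
        b_s = rng.normal(0, spec.shape_amplitude, gen.shape_modes.shape[1])
        b_g = rng.normal(0, spec.texture_amplitude, gen.n_texture_modes)
        image, lm = syn.render_instance(gen, b_s, b_g, rng=rng)
        pose0 = model.reference_pose(lm)
        s, th = pose0.scale_theta()
        from .shape import PoseParams
        pose0 = PoseParams.from_similarity(
            s * (1 + rng.uniform(-0.05, 0.05)),
            th + np.deg2rad(rng.uniform(-5, 5)),
            pose0.t_x + rng.uniform(-3, 3), pose0.t_y + rng.uniform(-3, 3))
        p, _E, _trace = fit(image, model,
                            FitParams(c=np.zeros(model.k_c), pose=pose0),
                            max_iter=30)
        S = posed_shape(model, p, image.shape)
        lm_errors.append(np.median(np.linalg.norm(
            S.points() - lm.points(), axis=1)))
        t_errors.append(float(np.hypot(
            *(S.points().mean(axis=0) - lm.points().mean(axis=0)))))
    t_errors = np.asarray(t_errors)
    return {"median_landmark_error_px": float(np.median(lm_errors)),
            "median_translation_error_px": float(np.median(t_errors)),
            "max_translation_error_px": float(np.max(t_errors)),
            "fraction_within_half_px": float(np.mean(t_errors <= 0.5)),
            "n": n_trials}


def tracking_drift(seed: int = 0, n_frames: int = 20,
                   drift: float = 0.5, iterations: int = 10) -> dict:
    """Track a drifting sequence with the fixed per-frame iteration protocol."""
    gen, model = _trained_face_model(seed)
    traj = syn.drift_trajectory(gen, n_frames, drift=(drift, 0.0))
    frames = syn.make_sequence(gen, traj, rng=np.random.default_rng(seed + 3))
    p0 = FitParams(c=np.zeros(model.k_c),
                   pose=model.reference_pose(frames[0][1]))
    results = track([img for img, _lm in frames], model, p0,
                    iterations=iterations)
    errors = []
    for (p, _E), (img, lm) in zip(results, frames):
        S = posed_shape(model, p, img.shape)
        errors.append(float(np.hypot(
            *(S.points().mean(axis=0) - lm.points().mean(axis=0)))))
    within = int(sum(e <= 1.0 for e in errors))
    return {"translation_errors_px": errors, "frames_within_1px": within,
            "n": n_frames}


def compute_cost_scaling(seed: int = 0, sizes=SWEEP_SIZES,
                         repeats: int = 11, inner: int = 3) -> dict:
    """Serial compute-E cost across the resolution sweep, with a linear fit.

    The per-iteration cost should grow linearly in the pixel count; R^2 of
    the least-squares line quantifies that.  Absolute times depend on the
    host and are not meaningful beyond the trend.  Each measurement times
    ``inner`` back-to-back evaluations and the minimum over ``repeats``
    measurements is kept, which suppresses scheduler noise.
    """
    rng = np.random.default_rng(seed)
    cases = []
    for npx in sizes:
        gen = syn.make_generator(syn.SyntheticSpec(
            target_pixels=npx, rng_seed=int(rng.integers(2**31))))
        model = syn.as_aam_model(gen)
        image, p = _perturbed_params(model, gen, rng)
        compute_residual(image, model, p)          # warm up
        cases.append((model, image, p))
    # round-robin over sizes so a transient load spike cannot contaminate
    # every repeat of one size
    best = np.full(len(cases), np.inf)
    for _ in range(repeats):
        for i, (model, image, p) in enumerate(cases):
            t0 = time.perf_counter()
            for _ in range(inner):
                compute_residual(image, model, p)
            best[i] = min(best[i], (time.perf_counter() - t0) / inner)
    pixels = [model.n_pixels for model, _img, _p in cases]
    times = list(best)
    x = np.asarray(pixels, dtype=float)
    t = np.asarray(times)
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, t, rcond=None)
    resid = t - A @ coef
    ss_tot = float((t - t.mean()) @ (t - t.mean()))
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return {"r_squared": r2, "pixels": pixels, "seconds": times,
            "slope_us_per_pixel": float(coef[0] * 1e6), "n": len(sizes)}
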