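# aamfit

Active appearance models (AAMs) for deformable-object analysis in grayscale
images: training statistical shape+texture models from landmarked images,
fitting them to new images, tracking through frame sequences — and a
deterministic emulation of the fine-grained data-parallel decomposition of
the fitting hotspot, so the parallel execution model can be verified
numerically against the serial reference.

## Who this is for

Image-analysis practitioners who need a model-based detector/tracker for
deformable objects (the classic application is faces with 68 landmarks), and
anyone studying how the AAM error computation decomposes into per-vertex and
per-pixel data-parallel stages with deterministic tree reductions.

## The model

A shape is the vector of n landmark coordinates, s = (x1..xn, y1..yn)ᵀ.
Training shapes are aligned by generalized Procrustes analysis and reduced by
PCA, s = s0 + Ps·bs.  Each training image is warped over a Delaunay
triangulation of the mean shape into a "shape-free patch", raster-scanned
into a texture vector, photometrically normalized (g = (g_im − β1)/α, with
β the mean intensity and α the projection onto the mean texture g0), and
reduced by a second PCA, g = g0 + Pg·bg.  A third PCA over the concatenated
(weighted) parameter vectors couples the two:

    s = s0 + Qs·c,      g = g0 + Qg·c

Fitting minimizes E(p) = rᵀr where r(p) = g_s − g_m is the residual between
the normalized image sample g_s and the model texture g_m, over
p = (c | t | u) (appearance, pose t = (s_x, s_y, t_x, t_y) with
s_x = s·cosθ − 1, s_y = s·sinθ, and photometric u).  The update is the fixed
linear regression Δp = −R·r, with R estimated once from displacement
experiments on the training set; each iteration accepts the first step
multiplier in (1, 1.5, 0.5, 0.25) that lowers E.

The parallel execution model distributes the five stages of computing E —
posed shape (one virtual thread per vertex), texture sampling (thread i
handles pixels i, i+N, …), the four-phase barrier-separated normalization,
model texture, and residual/error — over a virtual grid/block/thread
lattice.  All sums use a three-level plan (thread-local accumulation,
in-block stride-halving tree with exactly log2(block_dim) combine rounds,
cross-block accumulation in a fixed ascending order), and Δp uses an
autotuned wide matrix–vector kernel whose threads-per-row count adapts to
the matrix width.  The emulation reproduces the combine ordering and the
single/double precision switch exactly, so its results are bit-reproducible
and interchangeable with the serial path.

No external dataset is required: `aamfit.synthetic` generates landmarked
face-like images (68 landmarks, ~100 triangles, patch textures from 4096 to
65536 pixels) with exact shape/texture/pose ground truth.

## Worked example

```python
import numpy as np
import aamfit as A

# 1. synthesize a landmarked training set (68 landmarks, 4096-pixel patch)
spec = A.SyntheticSpec(rng_seed=5)
gen = A.make_generator(spec)
images, landmarks, _truth = A.make_training_set(gen, 30)

# 2. train the appearance model
model = A.train_aam(images, landmarks, target_pixels=4096, seed=1)
print(f"appearance modes k_c = {model.k_c}, patch pixels = {model.n_pixels}, "
      f"triangles = {len(model.patch_map.triangles)}")

# 3. fit a held-out instance from a displaced initialization
rng = np.random.default_rng(42)
b_s = rng.normal(0, spec.shape_amplitude, 3)
b_g = rng.normal(0, spec.texture_amplitude, 4)
image, lm = A.render_instance(gen, b_s, b_g, rng=rng)
pose0 = model.reference_pose(lm)       # detector-style initialization
pose0.t_x += 2.5
pose0.t_y -= 1.5
p, E, trace = A.fit(image, model, A.FitParams(c=np.zeros(model.k_c), pose=pose0))
S = A.fitting.posed_shape(model, p, image.shape)
err = np.linalg.norm(S.points() - lm.points(), axis=1)
print(f"converged in {len(trace) - 1} iterations, E {trace[0]:.1f} -> {E:.1f}")
print(f"median landmark error: {np.median(err):.3f} px")

# 4. the same error through the deterministic parallel emulation
st = A.par_compute_E(image, model, p, A.ExecConfig(grid_dim=4, block_dim=1024))
print(f"serial E = {E:.6f}, emulated-parallel E = {st.E:.6f}")
```

Output:

```
appearance modes k_c = 7, patch pixels = 4091, triangles = 92
converged in 6 iterations, E 1769.4 -> 16.7
median landmark error: 0.078 px
serial E = 16.700354, emulated-parallel E = 16.700354
```

The fit starts 2.9 px off and lands the 68 landmarks within a tenth of a
pixel of ground truth; the final E ≈ 16.7 is the noise floor set by the
generator's 1% sensor noise over ~4k pixels.  The serial and emulated
parallel error computations agree to the printed precision (their relative
difference is at rounding level in double precision).

## Command line

```sh
aam make-synthetic --out data --seed 3 --n-images 30 --frames 20
aam train --images data --landmarks data --target-pixels 4096 --out model.aam --seed 3
aam fit --model model.aam --image data/train_000.png --init "tx,ty,scale,theta" --out fit.json
aam track --model model.aam --frames data/frames --init "..." --out track.csv
aam bench --model model.aam --image data/train_000.png      # stage timing fractions
aam sweep --pixels 4096..65536:4096                          # resolution sweep
```

`aam bench` reports per-stage time fractions (informational only) and the
serial/parallel agreement on E; `aam sweep` measures the serial compute-E
cost across the 16-resolution regime and reports the linearity (R²) of cost
versus pixel count.

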