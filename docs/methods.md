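# Methods

This note documents the modeling and numerical choices behind `aamfit`: the
statistical models, the fitting procedure, the deterministic data-parallel
emulation, the synthetic-data generator that stands in for real landmarked
image sets, and the known limitations of each.

## Shape model

Shapes are 2n-vectors of landmark coordinates; model-frame vectors are laid
out (x1..xn, y1..yn), image-frame vectors interleaved (x1, y1, …), which is
the storage layout the per-vertex parallel stage assumes.

**Procrustes alignment.** Generalized Procrustes analysis under similarity
transforms, computed in complex form: the optimal similarity aligning z to
the mean m is a = ⟨z, m⟩/⟨z, z⟩, which excludes reflections by construction.
The mean is re-estimated until it moves by less than 1e-10 (Frobenius), then
fixed to the gauge: centroid at the origin, unit Frobenius norm, and the
landmark farthest from the centroid rotated onto the positive x-axis.  The
orientation gauge is intrinsic to the converged geometry, so the aligned
frame is invariant to any common similarity pre-applied to the inputs.  A
consequence worth knowing: the model frame's orientation is arbitrary
relative to any external coordinate convention, so fits should be seeded
with `AAMModel.reference_pose(landmarks)` (the least-squares similarity from
the mean shape to a landmark estimate — what a detector would provide).
Tangent-space projection, used by some of the alignment literature, is
deliberately omitted; at the shape variations considered here its effect is
far below the fitting noise floor.

**PCA conventions** (shared by all three PCAs). Eigenvalues below 1e-12 of
the largest — or below the cancellation noise of subtracting the sample mean,
≈(eps·‖X‖)² — are treated as exactly zero; the retained count is the
smallest whose cumulative eigenvalue fraction reaches `variance_retained`
(default 0.98, configurable; 1.0 keeps every nonzero mode and makes
reconstruction of the training set exact); mode count never exceeds
samples − 1; each eigenvector's sign is fixed so its first nonzero component
is positive, making serialized models byte-stable.

**Pose.** t = (s_x, s_y, t_x, t_y) with s_x = s·cosθ − 1, s_y = s·sinθ: the
identity is t = 0 and the transform is linear in the parameters, which is
what the regression update needs.  Composition and inversion are exact
(complex multiplication); a pose is invertible iff (1+s_x)² + s_y² > 0.

## Texture model

The shape-free patch is built once per model: Delaunay triangulation of the
mean shape (vertex-sorted and lexicographically ordered for
reproducibility), the mean shape scaled so the patch holds the requested
pixel count within 10% (fixed-point iteration on the count, which grows
quadratically with scale), and a per-pixel lookup of triangle index and
barycentric coordinates.  Pixels on shared edges go to the lowest triangle
index.  Pixel centers sit at integer coordinates, origin top-left,
x = column; intensities are floats in [0, 1] (8-bit images divided by 255);
images are grayscale only.

Sampling composes the barycentric warp (image position = α·v1 + β·v2 + γ·v3
over the triangle's vertices in the image-frame shape) with bilinear
interpolation.  Out-of-image positions are clamped to the border (edge
replication), never rejected — the posed shape itself is also clamped to the
image rectangle before sampling, so wild poses degrade gracefully instead of
failing.  One bilinear kernel backs both the serial and the emulated
parallel sampler, which is what makes their outputs bitwise identical.

**Photometric normalization.** g = (g_im − β·1)/α with β = mean(g_im) and
α = (g_im − β·1)·g0 / (g0·g0): the least-squares contrast/brightness match
of the sample to the mean texture.  The mean g0 is defined through a fixed
point (normalization is defined in terms of the mean): all samples are
normalized against the current estimate, averaged, and the average is
rescaled to the convention sum = 0, element variance = 1; iteration stops
when the mean moves by less than 1e-8 (at most 100 iterations, error
otherwise).  At the fixed point the average of the normalized samples equals
g0 exactly, because every normalized sample satisfies g·g0 = g0·g0.  A
sample orthogonal to the mean (α = 0) is an error: it carries no usable
texture.

## Combined appearance model

Per-example parameter vectors (w·bs | bg) undergo a third PCA, where the
scalar w = sqrt(total texture variance / total shape variance) balances the
two blocks' units.  The classical per-mode weighting matrix Ws is
deliberately reduced to this single scalar — with both sub-models already
whitened by their own PCAs the single scalar preserves the relative
variance budget, and it keeps the model container simple; it is configurable
per call.  The parameter vectors are projections of centered data, so their
sample mean is identically zero and the combined PCA is taken about the
origin; synthesis is then exactly s = s0 + Qs·c, g = g0 + Qg·c with
Qs = Ps·(Pc_s/w), Qg = Pg·Pc_g.

## Fitting

One residual evaluation: posed clamped shape → sampled texture → photometric
normalization → model texture → r = g_s − g_m, E = rᵀr.  Photometric
parameters default to analytic re-estimation inside the normalization each
evaluation (they are reported in the fit result); a flag instead carries
them in p and updates them through the regression like everything else.

**Gradient matrix.** Around each training example's ground-truth parameters,
random displacements are drawn within the perturbation ranges (defaults:
±3 px translation, ±5% scale, ±5° rotation, ±0.5 per-mode standard
deviations of c; ranges are a model-build parameter and are stored in the
container).  The residual is regressed on the displacement per pixel —
overdetermined, since experiments (≥3 per parameter by default) far exceed
parameters — giving the texture gradient G, and the update matrix is its
pseudo-inverse, R = G⁺, so Δp = −R·r.  Regressing in the opposite direction
(displacement on residual) is underdetermined in the pixel dimension; its
minimum-norm solution interpolates the experiments exactly and generalizes
poorly, which is why the gradient-then-invert construction is used.

**Search loop.** The loop body is the classical reconstruction: evaluate r
and E, propose Δp = −R·r, try step multipliers (1, 1.5, 0.5, 0.25) in order
and accept the first that lowers E by more than a relative 1e-10 (an E
below the rounding noise of the residual sum, n_pixels·(100·eps)², counts
as converged outright); stop when no multiplier improves E or after
`max_iter` iterations.  The multiplier schedule and the convergence rule
are a reconstruction of the standard procedure and are configurable.  With
`fixed_iterations=True` (the per-frame tracking protocol, 10 iterations per
frame by default) the trace always has `max_iter` entries; once no
multiplier improves, the remaining iterations are provably identical
no-ops, so the implementation pads the trace and exits early with the same
result.  Tracking seeds each frame with the previous frame's parameters;
the first frame's initialization must be supplied (automatic detection is
out of scope).

Accepted steps never increase E by construction; the per-iteration cost is
O(n_pixels × n_modes), dominated by the texture stages — the resolution
sweep in `experiments.compute_cost_scaling` measures exactly this linearity.

## Deterministic parallel emulation

The execution model is a virtual lattice of grid_dim blocks × block_dim
threads (block_dim a power of two; default 4×1024).  The contract the
emulation honors is the *numerics* of the decomposition, not concurrency:

- Elementwise stages (shape, sampling, model texture, residual) carry no
  cross-pixel arithmetic, so the strided thread mapping cannot change any
  operand; they run as whole-lattice array operations through the same
  kernels as the serial path and are bitwise identical to it at equal
  precision.
- Every sum follows the three-level plan literally: virtual thread t
  accumulates elements t, t+N, t+2N, … sequentially; each block reduces its
  block_dim workspace by a stride-halving tree (exactly log2(block_dim)
  combine rounds, asserted by an instrumented counter); block results are
  added in ascending block order.  The ascending order deterministically
  replaces a hardware atomic add whose ordering is nondeterministic — this
  is a documented deviation chosen for reproducibility; the equivalence
  tolerances absorb reordering effects when comparing precisions.
- The four normalization phases are separated by barriers (each phase
  completes over all data before the next).  Phase statistics use the
  per-element convention — mean, RMS norm of the centered texture, mean
  product with g0 — so for input g0 itself they are (0, 1, 1).  The phase
  output has mean(g·g0) = 1; the composed pipeline rescales by
  (g0·g0)/n — computed with the same reduction plan — which lands the
  texture in the model gauge and makes the pipeline agree with the serial
  residual to rounding (relative 1e-9 in double, 1e-5 in single precision,
  verified across patch sizes 4096–65536 and lattice geometries 1×32 to
  4×1024).
- The wide matrix–vector product for Δp picks threads-per-row as the
  smallest power of two whose per-thread segment is at most
  `segment_target` columns (default 512), capped at the thread count; the
  segmented partials combine through the same halving tree.

Precision is a global switch on `ExecConfig` (float64 for tests, float32 to
mirror single-precision reference arithmetic).  Shared-memory bank
geometry, caching, streams and occupancy are not modeled: none of them
affect numerics.  No claim about actual parallel performance is made or
measurable here — `aam bench` reports stage time fractions as qualitative
context only.

## Synthetic data

The generator emulates the face regime: 68 landmarks (elliptical outline
plus eye/nose/mouth clusters; a plain ellipse below 16 landmarks), ~100
Delaunay triangles, patches of 4096·i pixels (i = 1..16).  Shape modes are
random degree-≤3 polynomial displacement fields evaluated at the landmarks,
with the four similarity directions projected out (so pose and shape do not
confound) and orthonormalized.  Textures are band-limited 2-D cosine
mixtures, evaluated *continuously* during rendering, so rendering carries
no interpolation error of its own; at the canonical pose the patch lands on
integer image coordinates and the render→sample round trip is exact to
rounding, which anchors the self-consistency tests.  The mean field mixes
wavelengths from ~10 px up to the patch width with roughly 1/f amplitudes
and element std ≈ 0.12: the mid-frequency content plays the role of facial
detail, which is what localizes alignment — with a purely low-frequency
texture the error surface is nearly invariant to small misalignments (the
texture and photometric modes absorb them) and no fitting method localizes
well.  Per-example texture modes stay low-frequency (identity variation is
smooth), have unit per-pixel RMS, zero sum, and are orthogonal to the mean
texture, so the generator is itself an exact linear appearance model
(`as_aam_model` wraps it as one).

Defaults (the study conditions): 3 shape modes at amplitude 0.08 (~2 px of
landmark scatter at the 4096-pixel patch), 4 texture modes at amplitude
0.04 intensity units, additive Gaussian noise σ = 0.01 (~1% of the
intensity range), 30 training images with ±2 px / ±3% / ±0.05 rad pose
jitter and ±10% contrast, ±0.05 brightness jitter.  Everything is
deterministic given the seed.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: photorealistic facial appearance, identity-dependent
texture detail, occlusion, illumination gradients, landmark annotation
error, and background clutter.  Real-data fits will have higher landmark
errors and need detector-based initialization; the synthetic results bound
the method's behavior under its own assumptions, not its field accuracy.

## Experiment sizes

The packaged experiments use: 100 engine-equivalence triples split across
4096/16384/65536-pixel patches; reduction checks on 2^5..2^16 elements over
three lattice geometries; 50 mat-vec matrices spanning 10×100 to 64×65536;
50 recovery fits and 20 tracked frames on the default face model (30
training images); an 11-repeat, 3-call-inner, round-robin timing protocol
for the 16-point scaling sweep (minimum per size, which suppresses
scheduler noise).  These sizes keep a full run in the tens of seconds on
one CPU while leaving each measured margin orders of magnitude from its
bound.

## Known limitations

- Single-resolution models only; no multi-resolution pyramid, so the
  capture range is set by the texture detail scale and the gradient-matrix
  training ranges (a few pixels).
- The fixed regression matrix R is a global linearization: fits initialized
  at the corners of the perturbation range occasionally stall a few pixels
  from the optimum (no step multiplier improves E).  Median recovery errors
  on synthetic data are ~0.05 px, but individual trials are not guaranteed.
- Inverse-compositional fitting, robust error norms, color textures and
  occlusion handling are out of scope.
- The parallel engine is an emulation of an execution order; it makes no
  performance claims and does not model memory hierarchies.
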