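"""Shape-free texture patches: triangulation, warping, normalization, PCA.

Every training image is warped so its landmarks match the mean shape,
producing a "shape-free patch" whose pixels can be raster-scanned into a
texture vector g_im.  The warp is piecewise affine over a Delaunay
triangulation of the mean shape: each patch pixel carries the index of its
containing triangle and barycentric coefficients (alpha, beta, gamma), and its
image-frame position is the same barycentric combination of that triangle's
vertices in the image-frame shape.  Intensities are read with bilinear
interpolation.

Photometric (brightness/contrast) variation is removed by the linear
normalization g = (g_im - beta*1)/alpha, with beta the sample mean and alpha
the projection of the centered sample onto the mean texture g0.  The mean g0
itself is defined by a fixed point (normalization is defined in terms of the
mean) and scaled so its elements sum to zero with unit variance.

Conventions: pixel centers sit at integer coordinates, origin top-left,
x = column, y = row; intensities are held as floats (8-bit inputs divided by
255); samples falling outside the image are clamped to the border (edge
replication), never rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from ._pca import fit_pca
from .shape import IMAGE_FRAME, LandmarkShape

_BARY_EPS = 1e-10


@dataclass
class TextureVector:
    """Raster-scanned intensities over the shape-free patch."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("texture values must be finite")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class PhotometricParams:
    """Contrast (alpha_p) and brightness (beta_p) of the linear intensity map."""

    alpha_p: float = 1.0
    beta_p: float = 0.0


@dataclass
class TexturePCAModel:
    g0: TextureVector               # mean normalized texture
    Pg: np.ndarray                  # (n_pixels, k_g) orthonormal columns
    eigenvalues: np.ndarray
    total_variance: float = 0.0

    @property
    def n_modes(self) -> int:
        return self.Pg.shape[1]


@dataclass
class PatchMap:
    """Pixel-to-triangle lookup table of the shape-free patch.

    ``patch_points`` is the mean shape scaled/translated into patch pixel
    coordinates; ``rows``/``cols`` are the integer patch coordinates of the
    interior pixels in raster order; ``tri_index`` and ``bary`` locate each
    pixel inside its triangle.
    """

    triangles: np.ndarray       # (T, 3) vertex index triples
    patch_points: np.ndarray    # (n, 2) mean-shape vertices, patch frame
    rows: np.ndarray            # (n_pixels,) int
    cols: np.ndarray            # (n_pixels,) int
    tri_index: np.ndarray       # (n_pixels,) int
    bary: np.ndarray            # (n_pixels, 3)
    height: int
    width: int
    scale: float                # model frame -> patch frame scale factor
    offset: np.ndarray          # model frame -> patch frame translation

    @property
    def pixel_count(self) -> int:
        return self.tri_index.size


def _values(g) -> np.ndarray:
    return g.values if isinstance(g, TextureVector) else np.asarray(g).ravel()


def _triangle_areas(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p = points[triangles]
    v1, v2 = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
    return 0.5 * np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])


def triangulate_mean_shape(s0: LandmarkShape) -> np.ndarray:
    """Delaunay triangulation of the mean-shape landmarks.

    Triangles are returned with sorted vertex indices in lexicographic order,
    so the triangulation (and everything built on it) is reproducible.
    """
    pts = s0.points()
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError("cannot triangulate: landmark set is collinear "
                         "or otherwise degenerate") from exc
    simplices = np.sort(tri.simplices, axis=1)
    simplices = simplices[np.lexsort(simplices.T[::-1])]
    areas = _triangle_areas(pts, simplices)
    simplices = simplices[areas > 0]
    if simplices.size == 0:
        raise ValueError("triangulation produced no non-degenerate triangle")
    return np.ascontiguousarray(simplices)


def _rasterize(points: np.ndarray, triangles: np.ndarray, height: int, width: int):
    """Assign pixel centers to triangles (lowest triangle index wins on ties)."""
    tri_of = np.full((height, width), -1, dtype=np.int64)
    bary_of = np.zeros((height, width, 3))
    for t, (i, j, k) in enumerate(triangles):
        v0, v1, v2 = points[i], points[j], points[k]
        lo = np.floor(np.minimum(np.minimum(v0, v1), v2)).astype(int)
        hi = np.ceil(np.maximum(np.maximum(v0, v1), v2)).astype(int)
        x0, y0 = np.maximum(lo, 0)
        x1 = min(hi[0], width - 1)
        y1 = min(hi[1], height - 1)
        if x1 < x0 or y1 < y0:
            continue
        ys, xs = np.mgrid[y0:y1 + 1, x0:x1 + 1]
        # barycentric coordinates from the 2x2 system in (v1-v0, v2-v0)
        d = np.stack([xs - v0[0], ys - v0[1]], axis=-1).astype(np.float64)
        e1, e2 = v1 - v0, v2 - v0
        det = e1[0] * e2[1] - e1[1] * e2[0]
        beta = (d[..., 0] * e2[1] - d[..., 1] * e2[0]) / det
        gamma = (e1[0] * d[..., 1] - e1[1] * d[..., 0]) / det
        alpha = 1.0 - beta - gamma
        inside = ((alpha >= -_BARY_EPS) & (beta >= -_BARY_EPS)
                  & (gamma >= -_BARY_EPS) & (tri_of[y0:y1 + 1, x0:x1 + 1] < 0))
        sub_tri = tri_of[y0:y1 + 1, x0:x1 + 1]
        sub_tri[inside] = t
        sub_bary = bary_of[y0:y1 + 1, x0:x1 + 1]
        sub_bary[inside] = np.stack([alpha, beta, gamma], axis=-1)[inside]
    rows, cols = np.nonzero(tri_of >= 0)
    return rows, cols, tri_of[rows, cols], bary_of[rows, cols]


def build_patch_map(s0: LandmarkShape, triangles, target_pixels: int,
                    margin: float = 2.0, rel_tol: float = 0.10,
                    max_iter: int = 25) -> PatchMap:
    """Scale the mean shape so the patch holds ~``target_pixels`` interior pixels.

    The scale is refined by fixed-point iteration on the pixel count (count
    grows quadratically with scale) until it lands within ``rel_tol`` of the
    target.
    """
    if target_pixels < 64:
        raise ValueError("target_pixels must be at least 64")
    triangles = np.asarray(triangles, dtype=np.int64)
    pts0 = s0.points()
    area = _triangle_areas(pts0, triangles).sum()
    if area <= 0:
        raise ValueError("mean shape triangulation has zero area")
    scale = float(np.sqrt(target_pixels / area))
    best = None
    for _ in range(max_iter):
        pts = pts0 * scale
        offset = margin - pts.min(axis=0)
        pts = pts + offset
        width = int(np.ceil(pts[:, 0].max() + margin)) + 1
        height = int(np.ceil(pts[:, 1].max() + margin)) + 1
        rows, cols, tri_idx, bary = _rasterize(pts, triangles, height, width)
        count = rows.size
        if best is None or abs(count - target_pixels) < abs(best[0] - target_pixels):
            best = (count, scale)
        if count and abs(count - target_pixels) <= rel_tol * target_pixels:
            return PatchMap(triangles=triangles, patch_points=pts,
                            rows=rows, cols=cols, tri_index=tri_idx, bary=bary,
                            height=height, width=width, scale=scale,
                            offset=offset)
        if count == 0:
            scale *= 2.0
        else:
            scale *= float(np.sqrt(target_pixels / count))
    raise ValueError(
        f"could not reach {target_pixels} pixels within {rel_tol:.0%}; "
        f"nearest achievable was {best[0]} pixels")


def bilinear_sample(image: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear interpolation with border clamping (edge replication).

    This single routine backs both the serial and the emulated-parallel
    sampling path, so the two are arithmetically identical by construction.
    """
    h, w = image.shape
    x = np.clip(x, 0.0, w - 1.0)
    y = np.clip(y, 0.0, h - 1.0)
    x0 = np.minimum(np.floor(x), max(w - 2, 0)).astype(np.int64)
    y0 = np.minimum(np.floor(y), max(h - 2, 0)).astype(np.int64)
    fx = (x - x0).astype(image.dtype, copy=False)
    fy = (y - y0).astype(image.dtype, copy=False)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    top = (1 - fx) * image[y0, x0] + fx * image[y0, x1]
    bot = (1 - fx) * image[y1, x0] + fx * image[y1, x1]
    return (1 - fy) * top + fy * bot


def warp_positions(S_points: np.ndarray, pmap: PatchMap,
                   dtype=np.float64) -> np.ndarray:
    """Image-frame position of every patch pixel under the piecewise-affine warp."""
    verts = np.asarray(S_points, dtype=dtype)[pmap.triangles[pmap.tri_index]]
    bary = pmap.bary.astype(dtype, copy=False)
    return np.einsum("pk,pkc->pc", bary, verts)


def sample_texture(image: np.ndarray, S: LandmarkShape, pmap: PatchMap,
                   dtype=np.float64) -> TextureVector:
    """Sample the image under shape ``S`` into a raster-scanned texture vector."""
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale image")
    if np.isnan(img).any():
        raise ValueError("image contains NaN")
    if S.frame != IMAGE_FRAME:
        raise ValueError("sample_texture expects an image-frame shape")
    if S.n_points != pmap.patch_points.shape[0]:
        raise ValueError("shape/patch-map landmark counts differ")
    img = img.astype(dtype, copy=False)
    pos = warp_positions(S.points(), pmap, dtype)
    vals = bilinear_sample(img, pos[:, 0], pos[:, 1])
    return TextureVector(vals, normalized=False)


def standardize_texture(values) -> np.ndarray:
    """Offset and scale a vector to zero element sum and unit element variance."""
    v = _values(values).astype(np.float64)
    v = v - v.mean()
    var = float(np.mean(v * v))
    if var <= 0:
        raise ValueError("cannot standardize a constant texture")
    return v / np.sqrt(var)


def normalize_texture(g_im, g0) -> tuple[TextureVector, PhotometricParams]:
    """Photometric normalization against the mean texture.

    beta_p is the sample mean, alpha_p the least-squares contrast matching the
    centered sample to g0; the result satisfies sum(g) ~ 0 and
    dot(g, g0) = dot(g0, g0).
    """
    gv, g0v = _values(g_im), _values(g0)
    if gv.size != g0v.size:
        raise ValueError("texture length mismatch")
    beta = float(gv.mean())
    centered = gv - beta
    denom = float(g0v @ g0v)
    alpha = float(centered @ g0v) / denom
    if abs(alpha) < 1e-12:
        raise ValueError("texture is orthogonal to the mean (alpha_p = 0)")
    return (TextureVector(centered / alpha, normalized=True),
            PhotometricParams(alpha_p=alpha, beta_p=beta))


def compute_mean_normalized_texture(samples, tol: float = 1e-8,
                                    max_iter: int = 100) -> TextureVector:
    """Fixed point of normalize-all-then-average, in the zero-sum/unit-variance gauge."""
    vals = [_values(s) for s in samples]
    if len(vals) < 2:
        raise ValueError("need at least 2 texture samples")
    mean = standardize_texture(np.mean([standardize_texture(v) for v in vals],
                                       axis=0))
    delta = np.inf
    for _ in range(max_iter):
        normed = [normalize_texture(v, mean)[0].values for v in vals]
        new = standardize_texture(np.mean(normed, axis=0))
        delta = float(np.linalg.norm(new - mean))
        mean = new
        if delta < tol:
            return TextureVector(mean, normalized=True)
    raise ValueError(
        f"texture mean iteration did not converge (last delta {delta:.3e})")


def build_texture_pca(normalized, variance_retained: float = 0.98) -> TexturePCAModel:
    """PCA of normalized texture samples; the stored mean is their sample mean."""
    vals = [_values(s) for s in normalized]
    if len(vals) < 2:
        raise ValueError("texture PCA requires at least 2 samples")
    res = fit_pca(np.stack(vals), variance_retained, center=True)
    return TexturePCAModel(g0=TextureVector(res.mean, normalized=True),
                           Pg=res.components, eigenvalues=res.eigenvalues,
                           total_variance=res.total_variance)
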