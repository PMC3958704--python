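"""Landmark shapes, Procrustes alignment, shape PCA and pose transforms.

A shape is the vector of the 2-D coordinates of ``n`` labelled landmark
points.  Training shapes are brought into a common *model frame* (centroid at
the origin, unit Frobenius norm) by generalized Procrustes analysis under
similarity transforms, and their remaining variation is captured by PCA:

    s = s0 + Ps . b_s

where ``s0`` is the mean shape, the columns of ``Ps`` are orthonormal modes of
variation and ``b_s`` are the shape parameters.

The mapping from model frame to image frame is a similarity transform
parameterized linearly for fitting purposes as t = (s_x, s_y, t_x, t_y) with
s_x = s*cos(theta) - 1 and s_y = s*sin(theta), so the identity transform is
t = 0.

Storage convention: model-frame vectors are laid out (x1..xn, y1..yn);
image-frame vectors are interleaved (x1, y1, x2, y2, ...), which is the
layout the data-parallel shape stage assumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._pca import fit_pca

MODEL_FRAME = "model"
IMAGE_FRAME = "image"

_DEGENERATE_NORM = 1e-12


@dataclass
class LandmarkShape:
    """2n coordinates of n landmarks, in the model or the image frame."""

    coords: np.ndarray
    frame: str = MODEL_FRAME

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).ravel()
        if self.coords.size == 0 or self.coords.size % 2:
            raise ValueError("coords must hold 2*n_points values")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")
        if self.frame not in (MODEL_FRAME, IMAGE_FRAME):
            raise ValueError(f"unknown frame {self.frame!r}")

    @property
    def n_points(self) -> int:
        return self.coords.size // 2

    def points(self) -> np.ndarray:
        """Landmarks as an (n, 2) array of (x, y) rows."""
        n = self.n_points
        if self.frame == MODEL_FRAME:
            return np.column_stack([self.coords[:n], self.coords[n:]])
        return self.coords.reshape(n, 2)

    @classmethod
    def from_points(cls, points: np.ndarray, frame: str) -> "LandmarkShape":
        pts = np.asarray(points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("expected an (n, 2) point array")
        if frame == MODEL_FRAME:
            coords = np.concatenate([pts[:, 0], pts[:, 1]])
        else:
            coords = pts.reshape(-1)
        return cls(coords=coords, frame=frame)


@dataclass
class PoseParams:
    """Linearized similarity transform: s_x = s*cos(theta)-1, s_y = s*sin(theta)."""

    s_x: float = 0.0
    s_y: float = 0.0
    t_x: float = 0.0
    t_y: float = 0.0

    def as_vector(self) -> np.ndarray:
        return np.array([self.s_x, self.s_y, self.t_x, self.t_y])

    @classmethod
    def from_vector(cls, v) -> "PoseParams":
        v = np.asarray(v, dtype=np.float64).ravel()
        return cls(*(float(x) for x in v))

    @classmethod
    def from_similarity(cls, scale: float, theta: float,
                        t_x: float = 0.0, t_y: float = 0.0) -> "PoseParams":
        return cls(scale * np.cos(theta) - 1.0, scale * np.sin(theta),
                   float(t_x), float(t_y))

    def scale_theta(self) -> tuple[float, float]:
        a, b = 1.0 + self.s_x, self.s_y
        return float(np.hypot(a, b)), float(np.arctan2(b, a))


@dataclass
class ShapePCAModel:
    s0: LandmarkShape                 # mean shape, model frame
    Ps: np.ndarray                    # (2n, k_s) orthonormal columns
    eigenvalues: np.ndarray           # (k_s,), nonincreasing
    total_variance: float = 0.0       # sum of all nonzero eigenvalues

    @property
    def n_modes(self) -> int:
        return self.Ps.shape[1]


def _centered_complex(shape: LandmarkShape, index: int) -> np.ndarray:
    """Shape as a centered complex vector; raises on degenerate input."""
    pts = shape.points()
    z = (pts[:, 0] + 1j * pts[:, 1]) - complex(*pts.mean(axis=0))
    if np.linalg.norm(z) < _DEGENERATE_NORM:
        raise ValueError(f"shape {index} is degenerate (all landmarks coincide)")
    return z


def _from_complex(z: np.ndarray, frame: str = MODEL_FRAME) -> LandmarkShape:
    return LandmarkShape.from_points(np.column_stack([z.real, z.imag]), frame)


def procrustes_align(shapes, tol: float = 1e-10, max_iter: int = 200):
    """Generalized Procrustes alignment under similarity transforms.

    Returns ``(aligned, mean)``.  The mean has its centroid at the origin and
    unit Frobenius norm; each aligned shape is its input under the similarity
    transform that best matches it to the mean (complex least squares, which
    excludes reflections).  The mean is re-estimated until it moves by less
    than ``tol``.
    """
    shapes = list(shapes)
    if not shapes:
        raise ValueError("procrustes_align needs at least one shape")
    n = shapes[0].n_points
    for i, s in enumerate(shapes):
        if s.n_points != n:
            raise ValueError(
                f"shape {i} has {s.n_points} points, expected {n}")
    Z = [_centered_complex(s, i) for i, s in enumerate(shapes)]

    mean = Z[0] / np.linalg.norm(Z[0])
    for _ in range(max_iter):
        # optimal similarity a*z matching z to the mean: a = <z, m>/<z, z>
        aligned = [z * (np.vdot(z, mean) / np.vdot(z, z)) for z in Z]
        new = np.mean(aligned, axis=0)
        new -= new.mean()
        nrm = np.linalg.norm(new)
        if nrm < _DEGENERATE_NORM:
            raise ValueError("degenerate Procrustes mean (shapes cancel out)")
        new /= nrm
        if np.linalg.norm(new - mean) < tol:
            mean = new
            break
        mean = new
    # intrinsic orientation gauge: the landmark farthest from the centroid
    # sits on the positive x-axis, so the aligned frame does not depend on
    # how the inputs happened to be oriented
    anchor = mean[np.argmax(np.abs(mean))]
    mean = mean * (np.conj(anchor) / abs(anchor))
    aligned = [z * (np.vdot(z, mean) / np.vdot(z, z)) for z in Z]
    return [_from_complex(z) for z in aligned], _from_complex(mean)


def build_shape_pca(aligned, variance_retained: float = 0.98) -> ShapePCAModel:
    """PCA of Procrustes-aligned shapes (rows of the model-frame coordinate matrix)."""
    aligned = list(aligned)
    if len(aligned) < 2:
        raise ValueError("shape PCA requires at least 2 aligned shapes")
    X = np.stack([s.coords for s in aligned])
    res = fit_pca(X, variance_retained, center=True)
    return ShapePCAModel(
        s0=LandmarkShape(res.mean, MODEL_FRAME),
        Ps=res.components,
        eigenvalues=res.eigenvalues,
        total_variance=res.total_variance,
    )


def shape_from_params(model: ShapePCAModel, b_s) -> LandmarkShape:
    """Instantiate s = s0 + Ps . b_s in the model frame."""
    b_s = np.asarray(b_s, dtype=np.float64).ravel()
    if b_s.size != model.n_modes:
        raise ValueError(
            f"b_s has length {b_s.size}, model has {model.n_modes} modes")
    return LandmarkShape(model.s0.coords + model.Ps @ b_s, MODEL_FRAME)


def project_shape(model: ShapePCAModel, shape: LandmarkShape) -> np.ndarray:
    """Shape parameters b_s = Ps^T (s - s0) of a model-frame shape."""
    return model.Ps.T @ (shape.coords - model.s0.coords)


def apply_pose(shape: LandmarkShape, pose: PoseParams) -> LandmarkShape:
    """Map a model-frame shape into the image frame.

    Each point (x, y) goes to ((1+s_x)x - s_y*y + t_x, s_y*x + (1+s_x)y + t_y).
    """
    if shape.frame != MODEL_FRAME:
        raise ValueError("apply_pose expects a model-frame shape")
    pts = transform_points(shape.points(), pose)
    return LandmarkShape.from_points(pts, IMAGE_FRAME)


def transform_points(points: np.ndarray, pose: PoseParams) -> np.ndarray:
    a, b = 1.0 + pose.s_x, pose.s_y
    x, y = points[..., 0], points[..., 1]
    return np.stack([a * x - b * y + pose.t_x,
                     b * x + a * y + pose.t_y], axis=-1)


def invert_pose(pose: PoseParams) -> PoseParams:
    a, b = 1.0 + pose.s_x, pose.s_y
    d = a * a + b * b
    if d < _DEGENERATE_NORM:
        raise ValueError("pose is not invertible ((1+s_x)^2 + s_y^2 = 0)")
    ai, bi = a / d, -b / d
    return PoseParams(ai - 1.0, bi,
                      -(ai * pose.t_x - bi * pose.t_y),
                      -(bi * pose.t_x + ai * pose.t_y))


def compose_pose(outer: PoseParams, inner: PoseParams) -> PoseParams:
    """Pose of applying ``inner`` first, then ``outer``."""
    a2, b2 = 1.0 + outer.s_x, outer.s_y
    a1, b1 = 1.0 + inner.s_x, inner.s_y
    a, b = a2 * a1 - b2 * b1, a2 * b1 + b2 * a1
    tx = a2 * inner.t_x - b2 * inner.t_y + outer.t_x
    ty = b2 * inner.t_x + a2 * inner.t_y + outer.t_y
    return PoseParams(a - 1.0, b, tx, ty)


def estimate_pose(src: LandmarkShape, dst: LandmarkShape) -> PoseParams:
    """Least-squares similarity transform mapping ``src`` points onto ``dst``."""
    if src.n_points != dst.n_points:
        raise ValueError("point counts differ")
    zp, wp = src.points(), dst.points()
    z = zp[:, 0] + 1j * zp[:, 1]
    w = wp[:, 0] + 1j * wp[:, 1]
    zc, wc = z - z.mean(), w - w.mean()
    denom = np.vdot(zc, zc)
    if abs(denom) < _DEGENERATE_NORM:
        raise ValueError("source shape is degenerate")
    a = np.vdot(zc, wc) / denom
    t = w.mean() - a * z.mean()
    return PoseParams(a.real - 1.0, a.imag, t.real, t.imag)
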