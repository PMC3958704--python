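"""Combined appearance model coupling shape and texture.

Shape parameters b_s and texture parameters b_g of the training examples are
concatenated (with the shape block scaled by a single weight that balances the
total shape and texture variances, since the two live in different units) and
reduced by one further PCA.  The resulting appearance parameters c control
both halves at once:

    s = s0 + Qs . c,       g = g0 + Qg . c

where Qs and Qg fold the combined eigenvectors back through the shape and
texture bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._pca import fit_pca
from .shape import MODEL_FRAME, LandmarkShape, ShapePCAModel
from .texture import TexturePCAModel, TextureVector


@dataclass
class CombinedModel:
    shape: ShapePCAModel
    texture: TexturePCAModel
    Qs: np.ndarray              # (2n, k_c)
    Qg: np.ndarray              # (n_pixels, k_c)
    Pc_shape: np.ndarray        # (k_s, k_c) combined eigenvector rows, shape block
    Pc_texture: np.ndarray      # (k_g, k_c) combined eigenvector rows, texture block
    shape_weight: float
    eigenvalues: np.ndarray     # (k_c,), nonincreasing

    @property
    def k_c(self) -> int:
        return self.Qs.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.Qg.shape[0]


@dataclass
class ModelInstance:
    shape: LandmarkShape        # model frame
    texture: TextureVector      # normalized frame


def default_shape_weight(shape: ShapePCAModel, texture: TexturePCAModel) -> float:
    """Balance the total texture variance against the total shape variance."""
    if shape.total_variance <= 0:
        return 1.0
    return float(np.sqrt(texture.total_variance / shape.total_variance))


def build_combined_model(shape: ShapePCAModel, texture: TexturePCAModel,
                         b_s_all, b_g_all, variance_retained: float = 0.98,
                         shape_weight: float | None = None) -> CombinedModel:
    """Third PCA over the per-example (weighted shape | texture) parameter rows.

    The parameter vectors are projections onto centered bases, so their sample
    means are identically zero and the combined PCA is taken about the origin.
    """
    b_s_all = np.atleast_2d(np.asarray(b_s_all, dtype=np.float64))
    b_g_all = np.atleast_2d(np.asarray(b_g_all, dtype=np.float64))
    if b_s_all.shape[0] != b_g_all.shape[0]:
        raise ValueError("shape/texture example counts differ")
    if b_s_all.shape[1] != shape.n_modes or b_g_all.shape[1] != texture.n_modes:
        raise ValueError("parameter dimensions do not match the sub-models")
    w = default_shape_weight(shape, texture) if shape_weight is None else float(shape_weight)

    X = np.hstack([w * b_s_all, b_g_all])
    if X.shape[1] == 0:
        k_s, k_g = shape.n_modes, texture.n_modes
        return CombinedModel(shape, texture,
                             Qs=np.zeros((shape.s0.coords.size, 0)),
                             Qg=np.zeros((texture.g0.values.size, 0)),
                             Pc_shape=np.zeros((k_s, 0)),
                             Pc_texture=np.zeros((k_g, 0)),
                             shape_weight=w, eigenvalues=np.zeros(0))
    res = fit_pca(X, variance_retained, center=False)
    k_s = shape.n_modes
    Pc_s, Pc_g = res.components[:k_s], res.components[k_s:]
    return CombinedModel(
        shape=shape, texture=texture,
        Qs=shape.Ps @ (Pc_s / w),
        Qg=texture.Pg @ Pc_g,
        Pc_shape=Pc_s, Pc_texture=Pc_g,
        shape_weight=w, eigenvalues=res.eigenvalues)


def synthesize(model: CombinedModel, c) -> ModelInstance:
    """Model instance (s, g) = (s0 + Qs c, g0 + Qg c)."""
    c = np.asarray(c, dtype=np.float64).ravel()
    if c.size != model.k_c:
        raise ValueError(f"c has length {c.size}, model has {model.k_c} modes")
    return ModelInstance(
        shape=LandmarkShape(model.shape.s0.coords + model.Qs @ c, MODEL_FRAME),
        texture=TextureVector(model.texture.g0.values + model.Qg @ c,
                              normalized=True))


def model_texture(model: CombinedModel, c) -> TextureVector:
    """Texture half of the synthesis: g_m = g0 + Qg c."""
    c = np.asarray(c, dtype=np.float64).ravel()
    if c.size != model.k_c:
        raise ValueError(f"c has length {c.size}, model has {model.k_c} modes")
    return TextureVector(model.texture.g0.values + model.Qg @ c,
                         normalized=True)


def project_instance(model: CombinedModel, shape: LandmarkShape,
                     texture: TextureVector) -> np.ndarray:
    """Appearance parameters of a (model-frame shape, normalized texture) pair."""
    b_s = model.shape.Ps.T @ (shape.coords - model.shape.s0.coords)
    b_g = model.texture.Pg.T @ (texture.values - model.texture.g0.values)
    return project_params(model, b_s, b_g)


def project_params(model: CombinedModel, b_s, b_g) -> np.ndarray:
    x = np.concatenate([model.shape_weight * np.asarray(b_s, dtype=np.float64).ravel(),
                        np.asarray(b_g, dtype=np.float64).ravel()])
    return np.vstack([model.Pc_shape, model.Pc_texture]).T @ x
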