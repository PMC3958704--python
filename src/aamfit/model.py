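"""Trained model container and the end-to-end training pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import appearance, shape as shp, texture as tex
from .appearance import CombinedModel
from .texture import PatchMap


@dataclass
class AAMModel:
    """Everything a fit needs: the statistical models, the patch geometry and
    the regression (gradient) matrix."""

    combined: CombinedModel
    patch_map: PatchMap
    R: "object | None" = None          # fitting.GradientMatrix once estimated
    meta: dict = field(default_factory=dict)

    # convenience accessors -------------------------------------------------
    @property
    def s0(self):
        return self.combined.shape.s0

    @property
    def g0(self):
        return self.combined.texture.g0

    @property
    def Qs(self) -> np.ndarray:
        return self.combined.Qs

    @property
    def Qg(self) -> np.ndarray:
        return self.combined.Qg

    @property
    def k_c(self) -> int:
        return self.combined.k_c

    @property
    def n_pixels(self) -> int:
        return self.patch_map.pixel_count

    @property
    def n_points(self) -> int:
        return self.s0.n_points

    def reference_pose(self, landmarks):
        """Least-squares pose mapping the mean shape onto image landmarks.

        The standard way to seed a fit when landmark estimates (from a
        detector or ground truth) exist; it absorbs the orientation gauge of
        the model frame.
        """
        return shp.estimate_pose(self.s0, landmarks)


def train_aam(images, landmark_shapes, target_pixels: int = 4096,
              variance_shape: float = 0.98, variance_texture: float = 0.98,
              variance_combined: float = 0.98, seed: int = 0,
              estimate_gradient: bool = True,
              perturbation_spec=None, experiments_per_image: int | None = None,
              ) -> AAMModel:
    """Train a full appearance model from landmarked grayscale images.

    Pipeline: Procrustes alignment -> shape PCA -> Delaunay triangulation of
    the mean -> patch map at ``target_pixels`` -> texture sampling and
    photometric normalization -> texture PCA -> combined PCA -> gradient
    matrix regression (perturbation experiments around each training
    example's ground-truth parameters).
    """
    from . import fitting

    images = list(images)
    landmark_shapes = list(landmark_shapes)
    if len(images) != len(landmark_shapes):
        raise ValueError("image/landmark counts differ")
    if len(images) < 2:
        raise ValueError("training needs at least 2 examples")

    aligned, _mean = shp.procrustes_align(landmark_shapes)
    shape_model = shp.build_shape_pca(aligned, variance_shape)

    triangles = tex.triangulate_mean_shape(shape_model.s0)
    pmap = tex.build_patch_map(shape_model.s0, triangles, target_pixels)

    raw = [tex.sample_texture(np.asarray(img, dtype=np.float64), lm, pmap)
           for img, lm in zip(images, landmark_shapes)]
    g0_fp = tex.compute_mean_normalized_texture(raw)
    normalized, photos = [], []
    for g in raw:
        gn, ph = tex.normalize_texture(g, g0_fp)
        normalized.append(gn)
        photos.append(ph)
    texture_model = tex.build_texture_pca(normalized, variance_texture)

    b_s = np.stack([shp.project_shape(shape_model, s) for s in aligned])
    b_g = np.stack([texture_model.Pg.T @ (g.values - texture_model.g0.values)
                    for g in normalized])
    combined = appearance.build_combined_model(
        shape_model, texture_model, b_s, b_g, variance_combined)

    model = AAMModel(combined=combined, patch_map=pmap,
                     meta={"target_pixels": int(target_pixels),
                           "variance_shape": variance_shape,
                           "variance_texture": variance_texture,
                           "variance_combined": variance_combined,
                           "seed": int(seed),
                           "n_training": len(images)})

    if estimate_gradient:
        training = []
        for img, lm, bs_i, bg_i, ph in zip(images, landmark_shapes, b_s, b_g, photos):
            c = appearance.project_params(combined, bs_i, bg_i)
            inst = appearance.synthesize(combined, c)
            pose = shp.estimate_pose(inst.shape, lm)
            training.append((np.asarray(img, dtype=np.float64),
                             fitting.FitParams(c=c, pose=pose, photo=ph)))
        model.R = fitting.estimate_R(
            model, training,
            spec=perturbation_spec or fitting.PerturbationSpec(),
            seed=seed, experiments_per_image=experiments_per_image)
    return model
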