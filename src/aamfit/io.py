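"""Readers and writers: PTS landmark files, images, the model container.

The model container is a single-file ``.aam`` archive of named arrays (NumPy
zip format) plus a JSON metadata block; arrays round-trip bit-exactly and the
format version is checked on read.  All writes are atomic (write to a
temporary file in the same directory, then rename).
"""

from __future__ import annotations

import json
import os
import tempfile
import zipfile

import imageio.v3 as iio
import numpy as np

from .appearance import CombinedModel
from .fitting import GradientMatrix, PerturbationSpec
from .model import AAMModel
from .shape import IMAGE_FRAME, MODEL_FRAME, LandmarkShape, ShapePCAModel
from .texture import PatchMap, TexturePCAModel, TextureVector

MODEL_FORMAT = "aamfit-model"
MODEL_VERSION = 1


# --------------------------------------------------------------------------
# atomic writes

def _atomic_write(path: str, writer) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=os.path.basename(path))
    try:
        with os.fdopen(fd, "wb") as fh:
            writer(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# --------------------------------------------------------------------------
# PTS landmark files

def read_pts(path) -> LandmarkShape:
    """Parse a PTS landmark file (version/n_points header, points in braces)."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    def fail(lineno, msg):
        raise ValueError(f"{path}:{lineno}: {msg}")

    n_declared = None
    points = []
    state = "header"
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if state == "header":
            if line.startswith("version:"):
                continue
            if line.startswith("n_points:"):
                tok = line.split(":", 1)[1].strip()
                try:
                    n_declared = int(tok)
                except ValueError:
                    fail(lineno, f"malformed n_points value {tok!r}")
                continue
            if line == "{":
                if n_declared is None:
                    fail(lineno, "point list starts before n_points header")
                state = "points"
                continue
            fail(lineno, f"malformed header line {raw!r}")
        elif state == "points":
            if line == "}":
                state = "done"
                continue
            toks = line.split()
            if len(toks) != 2:
                fail(lineno, f"expected 'x y', got {raw!r}")
            try:
                points.append((float(toks[0]), float(toks[1])))
            except ValueError:
                fail(lineno, f"non-numeric coordinate in {raw!r}")
        else:
            fail(lineno, f"unexpected content after closing brace: {raw!r}")
    if state == "header":
        raise ValueError(f"{path}: no point list found")
    if state == "points":
        raise ValueError(f"{path}: point list not closed with '}}'")
    if len(points) != n_declared:
        raise ValueError(
            f"{path}: header declares n_points: {n_declared} but "
            f"{len(points)} points are listed")
    return LandmarkShape.from_points(np.array(points), IMAGE_FRAME)


def write_pts(path, shape: LandmarkShape) -> None:
    pts = shape.points()
    body = ["version: 1", f"n_points: {shape.n_points}", "{"]
    body += [f"{x:.6f} {y:.6f}" for x, y in pts]
    body.append("}")
    text = ("\n".join(body) + "\n").encode("utf-8")
    _atomic_write(str(path), lambda fh: fh.write(text))


# --------------------------------------------------------------------------
# images

def read_image(path) -> np.ndarray:
    """Grayscale float image in [0, 1]; color inputs are averaged to luminance."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    img = img.astype(np.float64)
    if img.max() > 1.0:
        img = img / (65535.0 if img.max() > 255 else 255.0)
    return img


def write_image(path, image: np.ndarray) -> None:
    img = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(str(path), np.round(img * 255).astype(np.uint8))


# --------------------------------------------------------------------------
# model container

def write_model(model: AAMModel, path) -> None:
    c = model.combined
    pm = model.patch_map
    meta = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "shape_weight": c.shape_weight,
        "shape_total_variance": c.shape.total_variance,
        "texture_total_variance": c.texture.total_variance,
        "patch": {"height": pm.height, "width": pm.width, "scale": pm.scale},
        "has_R": model.R is not None,
        "meta": model.meta,
    }
    arrays = {
        "s0": c.shape.s0.coords, "Ps": c.shape.Ps,
        "shape_eigenvalues": c.shape.eigenvalues,
        "g0": c.texture.g0.values, "Pg": c.texture.Pg,
        "texture_eigenvalues": c.texture.eigenvalues,
        "Qs": c.Qs, "Qg": c.Qg, "Pc_shape": c.Pc_shape,
        "Pc_texture": c.Pc_texture, "combined_eigenvalues": c.eigenvalues,
        "triangles": pm.triangles, "patch_points": pm.patch_points,
        "rows": pm.rows, "cols": pm.cols, "tri_index": pm.tri_index,
        "bary": pm.bary, "patch_offset": pm.offset,
    }
    if model.R is not None:
        meta["include_photo"] = model.R.include_photo
        meta["perturbation_spec"] = model.R.perturbation_spec.as_dict()
        arrays["R"] = model.R.R

    def writer(fh):
        np.savez(fh, meta_json=np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8), **arrays)

    _atomic_write(str(path), writer)


def read_model(path) -> AAMModel:
    try:
        data = np.load(path, allow_pickle=False)
    except (zipfile.BadZipFile, OSError, ValueError) as exc:
        raise ValueError(f"{path}: not a model container ({exc})") from exc
    with data:
        if "meta_json" not in data:
            raise ValueError(f"{path}: missing metadata block (wrong file type?)")
        meta = json.loads(bytes(data["meta_json"].tobytes()).decode("utf-8"))
        if meta.get("format") != MODEL_FORMAT:
            raise ValueError(f"{path}: unrecognized format {meta.get('format')!r}")
        if meta.get("version") != MODEL_VERSION:
            raise ValueError(
                f"{path}: unsupported container version {meta.get('version')} "
                f"(this build reads version {MODEL_VERSION})")
        a = {k: data[k] for k in data.files if k != "meta_json"}

    shape_model = ShapePCAModel(
        s0=LandmarkShape(a["s0"], MODEL_FRAME), Ps=a["Ps"],
        eigenvalues=a["shape_eigenvalues"],
        total_variance=meta["shape_total_variance"])
    texture_model = TexturePCAModel(
        g0=TextureVector(a["g0"], normalized=True), Pg=a["Pg"],
        eigenvalues=a["texture_eigenvalues"],
        total_variance=meta["texture_total_variance"])
    combined = CombinedModel(
        shape=shape_model, texture=texture_model, Qs=a["Qs"], Qg=a["Qg"],
        Pc_shape=a["Pc_shape"], Pc_texture=a["Pc_texture"],
        shape_weight=meta["shape_weight"],
        eigenvalues=a["combined_eigenvalues"])
    pmap = PatchMap(
        triangles=a["triangles"], patch_points=a["patch_points"],
        rows=a["rows"], cols=a["cols"], tri_index=a["tri_index"],
        bary=a["bary"], height=meta["patch"]["height"],
        width=meta["patch"]["width"], scale=meta["patch"]["scale"],
        offset=a["patch_offset"])
    model = AAMModel(combined=combined, patch_map=pmap, meta=meta["meta"])
    if meta.get("has_R"):
        model.R = GradientMatrix(
            R=a["R"], perturbation_spec=PerturbationSpec(**meta["perturbation_spec"]),
            include_photo=meta.get("include_photo", False))
    return model
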