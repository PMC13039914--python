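"""Preprocessing and artifact readers/writers.

Formats: PNG for images and heatmap overlays (visualization only — PNG
round-trips are lossy and never feed computation), ``.npy`` single-array
files for saliency maps and masks, JSON for reports and manifests, CSV for
grid tables, YAML for run configuration.  Every run directory receives the
resolved configuration and seed beside its outputs so any reported number
is recomputable from the directory contents alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import InputError, ParameterError
from .grid import Experiment
from .saliency import SaliencyMap

__all__ = [
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "load_image",
    "preprocess_image",
    "save_map",
    "load_map",
    "save_heatmap_png",
    "write_json",
    "grid_to_csv",
    "grid_from_csv",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


def load_image(path) -> np.ndarray:
    """Read a raster image as ``(H, W, C)`` float in [0, 1] (C = 1 or 3)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB")
        arr = np.asarray(im, dtype=np.float64) / 255.0
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return arr


def preprocess_image(
    image: np.ndarray,
    resize: int | None = 256,
    crop: int | None = 224,
    mean: tuple[float, ...] | None = None,
    std: tuple[float, ...] | None = None,
) -> np.ndarray:
    """Standard classifier preprocessing: resize, center-crop, standardize.

    The image is resampled to ``resize x resize``, center-cropped to
    ``crop x crop``, and channel-wise standardized with ``(v - mean)/std``.
    Any stage is skippable by passing ``None`` (fixture images typically
    skip resize/crop entirely).  Input and output are ``(H, W, C)`` float;
    input values are assumed already scaled to [0, 1].
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3:
        raise InputError(f"expected (H, W, C) image, got shape {arr.shape}")
    if resize is not None:
        pil = Image.fromarray((arr * 255).clip(0, 255).astype(np.uint8).squeeze())
        pil = pil.resize((resize, resize), Image.BILINEAR)
        arr = np.asarray(pil, dtype=np.float64) / 255.0
        if arr.ndim == 2:
            arr = arr[:, :, None]
    if crop is not None:
        h, w = arr.shape[:2]
        if crop > h or crop > w:
            raise ParameterError(f"crop {crop} larger than image ({h}, {w})")
        r0 = (h - crop) // 2
        c0 = (w - crop) // 2
        arr = arr[r0 : r0 + crop, c0 : c0 + crop]
    if mean is not None:
        c = arr.shape[2]
        mean_a = np.broadcast_to(np.asarray(mean, dtype=np.float64), (c,))
        std_a = np.broadcast_to(
            np.asarray(std if std is not None else 1.0, dtype=np.float64), (c,)
        )
        arr = (arr - mean_a) / std_a
    return arr


def save_map(smap: SaliencyMap, path) -> None:
    """Write a map as a raw single-array ``.npy`` file (lossless)."""
    np.save(path, smap.values)


def load_map(path) -> SaliencyMap:
    arr = np.load(path, allow_pickle=False)
    return SaliencyMap(arr)


def save_heatmap_png(
    smap: SaliencyMap,
    path,
    image: np.ndarray | None = None,
    cmap: str = "jet",
    alpha: float = 0.5,
) -> None:
    """8-bit heatmap PNG, optionally alpha-blended over the source image.

    Presentation only: colormap and alpha never feed any computation.
    """
    from matplotlib import colormaps

    v = smap.values
    lo, hi = v.min(), v.max()
    norm = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    rgba = colormaps[cmap](norm)
    rgb = rgba[:, :, :3]
    if image is not None:
        base = np.asarray(image, dtype=np.float64)
        if base.ndim == 3 and base.shape[2] == 1:
            base = np.repeat(base, 3, axis=2)
        rgb = (1 - alpha) * base + alpha * rgb
    Image.fromarray((rgb * 255).clip(0, 255).astype(np.uint8)).save(path)


def write_json(payload: dict, path) -> None:
    """Deterministic JSON (sorted keys, fixed float formatting via repr)."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def grid_to_csv(results: list[Experiment], path) -> None:
    """Grid table: one row per binary code (2^n rows)."""
    df = pd.DataFrame(
        {
            "code": [r.code for r in results],
            "methods": [",".join(r.methods) for r in results],
            "scorable": [r.scorable for r in results],
            "best_k": [r.best_k for r in results],
            "road": [r.road for r in results],
        }
    )
    df.to_csv(path, index=False)


def grid_from_csv(path) -> list[Experiment]:
    df = pd.read_csv(path, dtype={"code": str})
    out = []
    for row in df.itertuples(index=False):
        methods = tuple(str(row.methods).split(",")) if isinstance(row.methods, str) and row.methods else ()
        out.append(
            Experiment(
                code=str(row.code),
                methods=methods,
                scorable=bool(row.scorable),
                best_k=None if pd.isna(row.best_k) else float(row.best_k),
                road=None if pd.isna(row.road) else float(row.road),
            )
        )
    return out
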