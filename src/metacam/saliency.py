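"""Saliency-map data type and the normalization / thresholding primitives.

A :class:`SaliencyMap` is a 2-D grid of real activation intensities over
image pixels — the universal currency of the toolkit.  Every class
activation map, every ensemble, and every ROAD pixel selection operates on
this type.

Coordinate convention (used everywhere in the package): row-major, 0-based
pixel indices in ``(row, col)`` order; maps are ``(height, width)`` numpy
arrays of float64.

Percentile convention: all rank-based thresholds use the linear-interpolation
percentile of the flattened pixel values (numpy's default), so results are
invariant to pixel traversal order.  At the threshold, ties are kept: every
pixel whose value equals the percentile value is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InputError, ParameterError

__all__ = [
    "SaliencyMap",
    "normalize_unit",
    "topk_threshold",
    "upsample_bilinear",
]


@dataclass(frozen=True)
class SaliencyMap:
    """A 2-D grid of activation values over image pixels.

    Parameters
    ----------
    values
        ``(H, W)`` array of activation intensities (unitless).  Values may
        be non-finite; such a map is *invalid* and is expected to be dropped
        upstream (see :func:`metacam.ensemble.drop_invalid`).
    normalized
        When set, values are guaranteed to lie in ``[0, 1]``.
    """

    values: np.ndarray
    normalized: bool = False

    def __init__(self, values: np.ndarray, normalized: bool = False):
        arr = np.asarray(values, dtype=np.float64)
        if arr.ndim != 2:
            raise InputError(f"saliency map must be 2-D, got shape {arr.shape}")
        if arr.size == 0:
            raise InputError("saliency map must be non-empty")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "normalized", bool(normalized))

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def is_finite(self) -> bool:
        """True when every pixel value is finite (no NaN/Inf)."""
        return bool(np.isfinite(self.values).all())

    def is_all_zero(self) -> bool:
        return bool((self.values == 0).all())


def normalize_unit(smap: SaliencyMap) -> SaliencyMap:
    """Affinely rescale a map so its values span ``[0, 1]``.

    ``out = (v - min) / (max - min)``.  A constant map (``max == min``)
    degenerates to the all-zero map — a valid but uninformative map —
    rather than raising a division error.  Idempotent for non-constant maps.
    """
    v = smap.values
    if not np.isfinite(v).all():
        raise InputError("cannot normalize a map with non-finite values")
    lo = v.min()
    hi = v.max()
    if hi == lo:
        return SaliencyMap(np.zeros_like(v), normalized=True)
    return SaliencyMap((v - lo) / (hi - lo), normalized=True)


def topk_threshold(smap: SaliencyMap, k: float) -> SaliencyMap:
    """Keep the top-``k``% most activated pixels, zeroing all others.

    The threshold ``t`` is the ``(100 - k)``-th linear-interpolation
    percentile of the flattened pixel values.  Pixels with value ``>= t``
    are retained verbatim; ties at the threshold are all kept, so the
    surviving set may exceed ``k``% of pixels.  ``k=100`` is the identity.
    """
    if not (0 < k <= 100):
        raise ParameterError(f"k must be in (0, 100], got {k}")
    v = smap.values
    if not np.isfinite(v).all():
        raise InputError("cannot threshold a map with non-finite values")
    t = np.percentile(v, 100.0 - k)
    out = np.where(v >= t, v, 0.0)
    # thresholding cannot push normalized values outside [0, 1]
    return SaliencyMap(out, normalized=smap.normalized and v.min() >= 0)


def upsample_bilinear(smap: SaliencyMap, target_h: int, target_w: int) -> SaliencyMap:
    """Bilinearly resample a map to ``(target_h, target_w)``.

    Uses align-corners coordinate mapping (source position
    ``i * (H-1) / (target_h-1)``), so constant maps stay exactly constant
    and resampling to the same shape is the identity.
    """
    if target_h <= 0 or target_w <= 0:
        raise ParameterError(
            f"target dims must be positive, got ({target_h}, {target_w})"
        )
    h, w = smap.shape
    if (h, w) == (target_h, target_w):
        return smap
    rows = (
        np.linspace(0.0, h - 1.0, target_h) if target_h > 1 else np.zeros(1)
    )
    cols = (
        np.linspace(0.0, w - 1.0, target_w) if target_w > 1 else np.zeros(1)
    )
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = ndimage.map_coordinates(
        smap.values, [rr, cc], order=1, mode="nearest"
    )
    return SaliencyMap(out, normalized=smap.normalized)

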