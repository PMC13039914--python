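"""Consensus ensembling of class activation maps.

Three ways to combine ``n`` normalized component maps:

* **mean** — pixelwise average, renormalized.
* **weighted** — pixelwise weighted average ``sum(w_n * L_n) / sum(w_n)``
  with nonnegative per-map weights (typically derived from each map's ROAD
  score via a weight transform), renormalized.
* **consensus** — pixelwise *sum* followed by top-k% thresholding: only
  pixels whose summed activation reaches the ``(100-k)``-th percentile
  survive, so a pixel must be highly activated in *agreement* across
  components to be kept.  This is the MetaCAM formulation: a component that
  highlights the wrong region is simply outvoted.

Because the best ``k`` depends on the image, class, and model, an adaptive
search scores the thresholded map at every candidate ``k`` with ROAD and
returns the argmax; the same search applied to a single component map
refines that individual method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cams import CamResult
from .errors import EnsembleError, InputError, ParameterError
from .models import ModelAdapter
from .road import RoadConfig, road_score
from .saliency import SaliencyMap, normalize_unit, topk_threshold

__all__ = [
    "DEFAULT_K_GRID",
    "EnsembleConfig",
    "AdaptiveResult",
    "drop_invalid",
    "mean_ensemble",
    "weight_transform",
    "weighted_ensemble",
    "consensus_metacam",
    "adaptive_threshold_search",
]

DEFAULT_K_GRID: tuple[float, ...] = tuple(range(5, 100, 5))

_MODES = ("mean", "weighted", "consensus")
_TRANSFORMS = ("none", "minmax", "softmax_amplified", "exponential")


@dataclass(frozen=True)
class EnsembleConfig:
    """How component maps are combined.

    ``k_grid`` defaults to 5..95 in steps of 5: wide enough to bracket the
    typically useful 15-45 band while still catching very selective optima
    near k=10.
    """

    mode: str = "consensus"
    weight_transform: str = "none"
    k_grid: tuple[float, ...] = DEFAULT_K_GRID
    renormalize_output: bool = True

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ParameterError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.weight_transform not in _TRANSFORMS:
            raise ParameterError(
                f"weight_transform must be one of {_TRANSFORMS}, got "
                f"{self.weight_transform!r}"
            )
        for k in self.k_grid:
            if not (0 < k <= 100):
                raise ParameterError(f"k_grid value {k} outside (0, 100]")


@dataclass(frozen=True)
class AdaptiveResult:
    """Outcome of an adaptive top-k search."""

    best_k: float
    best_map: SaliencyMap
    scores_by_k: dict[float, float] = field(default_factory=dict)


def drop_invalid(results: Sequence[CamResult]) -> list[CamResult]:
    """Remove invalid component maps, preserving order.

    Invalid means: flagged by the method, non-finite, or all-zero.  If no
    map survives, raises :class:`EnsembleError` listing per-method reasons.
    """
    kept = []
    reasons = []
    for r in results:
        if r.valid and r.map.is_finite() and not r.map.is_all_zero():
            kept.append(r)
        else:
            reasons.append(f"{r.method}: {r.reason or 'all-zero or non-finite'}")
    if not kept:
        raise EnsembleError(
            "no valid component maps remain; reasons: " + "; ".join(reasons)
        )
    return kept


def _stack(maps: Sequence[SaliencyMap]) -> np.ndarray:
    if len(maps) == 0:
        raise EnsembleError("need at least one map")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise InputError(f"map shape mismatch: {m.shape} vs {shape}")
    return np.stack([m.values for m in maps])


def mean_ensemble(maps: Sequence[SaliencyMap]) -> SaliencyMap:
    """Pixelwise mean of normalized maps, renormalized to [0, 1]."""
    return normalize_unit(SaliencyMap(_stack(maps).mean(axis=0)))


def weight_transform(road_values: Sequence[float], mode: str = "none") -> np.ndarray:
    """Turn per-map quality scores into nonnegative ensemble weights.

    * ``none`` — raw values, shifted up to nonnegative if any are negative.
    * ``minmax`` — affine rescale to [0, 1]; equal values degenerate to
      uniform weights ``1/n``.
    * ``softmax_amplified`` — softmax of ``s * v`` where ``s`` is the
      smallest power of 10 making ``max |s * v| >= 10`` (amplification
      spreads near-tied small scores before the softmax).
    * ``exponential`` — ``exp(v) / sum exp(v)`` (softmax of the raw values).
    """
    v = np.asarray(road_values, dtype=np.float64)
    if v.ndim != 1 or v.size == 0:
        raise ParameterError("road_values must be a nonempty 1-D sequence")
    if not np.isfinite(v).all():
        raise ParameterError("road_values must be finite")
    if mode == "none":
        return v - v.min() if v.min() < 0 else v.copy()
    if mode == "minmax":
        if v.max() == v.min():
            return np.full(v.size, 1.0 / v.size)
        return (v - v.min()) / (v.max() - v.min())
    if mode == "softmax_amplified":
        s = 1.0
        if np.abs(v).max() > 0:
            while np.abs(s * v).max() < 10.0:
                s *= 10.0
        return _softmax(s * v)
    if mode == "exponential":
        return _softmax(v)
    raise ParameterError(f"unknown weight transform {mode!r}")


def _softmax(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - v.max())
    return e / e.sum()


def weighted_ensemble(
    maps: Sequence[SaliencyMap], weights: Sequence[float]
) -> SaliencyMap:
    """Weighted pixelwise mean ``sum(w_n * L_n) / sum(w_n)``, renormalized."""
    stack = _stack(maps)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (stack.shape[0],):
        raise InputError(f"{len(maps)} maps but weight shape {w.shape}")
    if (w < 0).any():
        raise ParameterError("weights must be nonnegative")
    total = w.sum()
    if total == 0:
        raise EnsembleError("all-zero weights: ensemble undefined")
    mean = np.tensordot(w, stack, axes=1) / total
    return normalize_unit(SaliencyMap(mean))


def consensus_metacam(
    maps: Sequence[SaliencyMap],
    k: float,
    renormalize_output: bool = True,
) -> SaliencyMap:
    """Top-k% consensus: sum the maps and keep only the top-k% of pixels.

    ``k=100`` reduces to a (re)normalized sum.  With ``renormalize_output``
    (default) the thresholded map is rescaled to [0, 1]; otherwise the
    surviving pixels keep their summed values.
    """
    summed = SaliencyMap(_stack(maps).sum(axis=0))
    out = topk_threshold(summed, k)
    return normalize_unit(out) if renormalize_output else out


def adaptive_threshold_search(
    maps: SaliencyMap | Sequence[SaliencyMap],
    model: ModelAdapter,
    image: np.ndarray,
    class_index: int,
    k_grid: Sequence[float] = DEFAULT_K_GRID,
    road_config: RoadConfig | None = None,
    renormalize_output: bool = True,
) -> AdaptiveResult:
    """Grid-search the top-k threshold maximizing the ROAD score.

    Accepts either an ensemble (sequence of maps, combined by consensus at
    each candidate ``k``) or a single map (thresholded directly — the
    refinement of an individual CAM).  Returns the argmax ``k`` with the
    full score table; ties break toward the smallest ``k`` (the most
    selective map at equal faithfulness).  Deterministic under a fixed
    ``road_config.seed``.
    """
    if isinstance(maps, SaliencyMap):
        maps = [maps]
    if len(list(maps)) == 0:
        raise EnsembleError("no maps to search over")
    if not k_grid:
        raise ParameterError("k_grid must be nonempty")
    road_config = road_config or RoadConfig()
    scores: dict[float, float] = {}
    best_map: dict[float, SaliencyMap] = {}
    for k in k_grid:
        candidate = consensus_metacam(maps, k, renormalize_output)
        scores[k] = road_score(model, image, class_index, candidate, road_config).combined
        best_map[k] = candidate
    best_k = min(
        scores, key=lambda kk: (-scores[kk], kk)
    )  # max score; ties -> smallest k
    return AdaptiveResult(best_k=best_k, best_map=best_map[best_k], scores_by_k=scores)
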