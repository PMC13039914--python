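"""Component visual-explanation methods behind one uniform interface.

All class activation maps follow the same skeleton: activations ``A_k`` at
a chosen layer are combined with per-channel weights (or elementwise
gradient products), passed through a ReLU, upsampled bilinearly to image
resolution, and min-max normalized to ``[0, 1]``.  Methods differ only in
how they weight the feature maps:

===================  ======================================================
gradcam              spatial mean of the class-logit gradients per channel
gradcampp            higher-order gradient weighting (GradCAM++)
xgradcam             activation-normalized gradient sums
hirescam             elementwise grad * activation, summed, then ReLU
gradcam_elementwise  ReLU of grad * activation per channel, then summed
layercam             positive gradients only, elementwise
scorecam             forward score of the input masked by each channel
ablationcam          relative score drop when each channel is zeroed
eigencam             first singular vector of the activation matrix
eigengradcam         first singular vector of grad * activation
fullgrad             input-gradient and bias-gradient decomposition
randomcam            i.i.d. uniform noise in [-1, 1] (a control method)
===================  ======================================================

Every result is a :class:`CamResult`: a normalized image-resolution map
with a validity flag.  Invalid outputs (all-zero, non-finite, unsupported
model) are flagged with a reason, never raised, so ensembles can drop them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CaptureError, InputError, ParameterError
from .models import ActivationBundle, ModelAdapter, softmax
from .saliency import SaliencyMap, normalize_unit, upsample_bilinear

__all__ = [
    "CAM_METHODS",
    "CamResult",
    "compute_cam",
    "channel_weights",
    "elementwise_map",
    "assemble_cam",
    "perturbation_cam",
    "eigen_cam",
    "fullgrad_map",
    "random_cam",
]

EPS = 1e-7

CAM_METHODS: tuple[str, ...] = (
    "gradcam",
    "gradcampp",
    "xgradcam",
    "eigengradcam",
    "hirescam",
    "gradcam_elementwise",
    "layercam",
    "scorecam",
    "ablationcam",
    "eigencam",
    "fullgrad",
    "randomcam",
)

_WEIGHTED = {"gradcam", "gradcampp", "xgradcam"}
_ELEMENTWISE = {"hirescam", "gradcam_elementwise", "layercam"}
_PERTURBATION = {"scorecam", "ablationcam"}
_EIGEN = {"eigencam", "eigengradcam"}


@dataclass(frozen=True)
class CamResult:
    """One method's saliency map, normalized at image resolution, or invalid."""

    method: str
    map: SaliencyMap
    valid: bool
    reason: str | None = None


def _invalid(method: str, shape: tuple[int, int], reason: str) -> CamResult:
    return CamResult(
        method=method,
        map=SaliencyMap(np.zeros(shape), normalized=True),
        valid=False,
        reason=reason,
    )


def _finalize(method: str, raw: np.ndarray, image_hw: tuple[int, int]) -> CamResult:
    """Upsample to image resolution, normalize, and flag degenerate outputs."""
    if not np.isfinite(raw).all():
        return _invalid(method, image_hw, "non-finite map")
    smap = upsample_bilinear(SaliencyMap(raw), *image_hw)
    if (smap.values == smap.values.flat[0]).all():
        # constant (incl. all-zero) maps normalize to all-zero: uninformative
        return _invalid(method, image_hw, "constant map")
    return CamResult(method=method, map=normalize_unit(smap), valid=True)


# ---------------------------------------------------------------------------
# gradient-based weightings
# ---------------------------------------------------------------------------


def channel_weights(method: str, bundle: ActivationBundle) -> np.ndarray:
    """Per-channel weights for the globally weighted CAM family."""
    a, g = bundle.feature_maps, bundle.gradients
    if method == "gradcam":
        return g.mean(axis=(1, 2))
    if method == "gradcampp":
        # alpha_k^{ij} = g^2 / (2 g^2 + sum_ij A g^3); w_k = sum alpha * relu(g)
        g2 = g * g
        denom = 2.0 * g2 + (a * g2 * g).sum(axis=(1, 2), keepdims=True)
        alpha = np.where(np.abs(denom) > EPS, g2 / np.where(denom == 0, 1.0, denom), 0.0)
        return (alpha * np.maximum(g, 0.0)).sum(axis=(1, 2))
    if method == "xgradcam":
        num = (g * a).sum(axis=(1, 2))
        return num / (a.sum(axis=(1, 2)) + EPS)
    raise ParameterError(f"{method!r} is not a channel-weighted method")


def elementwise_map(method: str, bundle: ActivationBundle) -> SaliencyMap:
    """Layer-resolution map for the elementwise-gradient CAM family."""
    a, g = bundle.feature_maps, bundle.gradients
    if method == "hirescam":
        raw = np.maximum((g * a).sum(axis=0), 0.0)
    elif method == "gradcam_elementwise":
        raw = np.maximum(g * a, 0.0).sum(axis=0)
    elif method == "layercam":
        raw = np.maximum((np.maximum(g, 0.0) * a).sum(axis=0), 0.0)
    else:
        raise ParameterError(f"{method!r} is not an elementwise method")
    return SaliencyMap(raw)


def assemble_cam(
    method: str,
    model: ModelAdapter,
    image: np.ndarray,
    layer: str | None = None,
    class_index: int | None = None,
) -> CamResult:
    """Gradient-based CAM: weight/combine -> ReLU -> upsample -> normalize."""
    layer, class_index = _resolve(model, image, layer, class_index)
    image_hw = image.shape[:2]
    try:
        bundle = model.capture(image, layer, class_index)
    except CaptureError as exc:
        return _invalid(method, image_hw, f"capture failed: {exc}")
    if method in _WEIGHTED:
        w = channel_weights(method, bundle)
        raw = np.maximum(
            (w[:, None, None] * bundle.feature_maps).sum(axis=0), 0.0
        )
    elif method in _ELEMENTWISE:
        raw = elementwise_map(method, bundle).values
    else:
        raise ParameterError(f"{method!r} is not a gradient-based CAM")
    return _finalize(method, raw, image_hw)


# ---------------------------------------------------------------------------
# perturbation-based methods
# ---------------------------------------------------------------------------


def perturbation_cam(
    method: str,
    model: ModelAdapter,
    image: np.ndarray,
    layer: str | None = None,
    class_index: int | None = None,
    score_softmax: bool = True,
) -> CamResult:
    """ScoreCAM / AblationCAM: channel importance from forward perturbations.

    ScoreCAM masks the input with each channel's normalized, upsampled
    activation and weights channels by the resulting target score
    (softmaxed over channels by default, ``score_softmax=False`` for raw
    scores).  AblationCAM zeroes each channel at the layer and weights by
    the relative drop ``(y_c - y_c^ablated) / y_c``.
    """
    if method not in _PERTURBATION:
        raise ParameterError(f"{method!r} is not a perturbation CAM")
    layer, class_index = _resolve(model, image, layer, class_index)
    image_hw = image.shape[:2]
    bundle = model.capture(image, layer, class_index)
    a = bundle.feature_maps
    k = a.shape[0]
    if method == "scorecam":
        scores = np.empty(k)
        for ch in range(k):
            chan = SaliencyMap(a[ch])
            up = upsample_bilinear(chan, *image_hw).values
            lo, hi = up.min(), up.max()
            mask = np.zeros_like(up) if hi == lo else (up - lo) / (hi - lo)
            scores[ch] = model.logits(image * mask[:, :, None])[class_index]
        weights = softmax(scores) if score_softmax else scores
    else:  # ablationcam
        y_c = float(model.logits(image)[class_index])
        if not hasattr(model, "logits_with_ablation"):
            return _invalid(method, image_hw, "model does not support channel ablation")
        weights = np.empty(k)
        denom = y_c if abs(y_c) > EPS else EPS
        for ch in range(k):
            y_abl = float(model.logits_with_ablation(image, layer, ch)[class_index])
            weights[ch] = (y_c - y_abl) / denom
    raw = np.maximum((weights[:, None, None] * a).sum(axis=0), 0.0)
    return _finalize(method, raw, image_hw)


# ---------------------------------------------------------------------------
# eigen methods
# ---------------------------------------------------------------------------


def eigen_projection(stack: np.ndarray) -> np.ndarray:
    """First-singular-vector projection of a ``(K, h, w)`` stack -> ``(h, w)``.

    Equals ``sigma_1 * v_1`` of the ``K x (h*w)`` matrix, with the sign
    chosen so the entry of maximum magnitude is positive.
    """
    k, h, w = stack.shape
    mat = stack.reshape(k, h * w)
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    proj = s[0] * vt[0]
    if np.abs(proj).max() > 0 and proj[np.argmax(np.abs(proj))] < 0:
        proj = -proj
    return proj.reshape(h, w)


def eigen_cam(
    method: str,
    bundle: ActivationBundle,
    image_hw: tuple[int, int],
) -> CamResult:
    """EigenCAM / EigenGradCAM from a captured bundle."""
    if method not in _EIGEN:
        raise ParameterError(f"{method!r} is not an eigen method")
    stack = (
        bundle.feature_maps
        if method == "eigencam"
        else bundle.gradients * bundle.feature_maps
    )
    if not np.any(stack):
        return _invalid(method, image_hw, "rank-0 activation matrix")
    return _finalize(method, eigen_projection(stack), image_hw)


# ---------------------------------------------------------------------------
# FullGrad
# ---------------------------------------------------------------------------


def fullgrad_map(
    model: ModelAdapter,
    image: np.ndarray,
    class_index: int | None = None,
) -> CamResult:
    """FullGrad: |input-gradient * input| plus per-layer |bias * bias-gradient|.

    Each term is post-processed (absolute value, upsample to image
    resolution, min-max normalize) and the terms are summed, then the sum
    is normalized again.  Requires the extended adapter contract
    (``full_gradients``); models without capturable biases yield an invalid
    result rather than an exception.
    """
    _, class_index = _resolve(model, image, None, class_index)
    image_hw = image.shape[:2]
    if not hasattr(model, "full_gradients"):
        return _invalid("fullgrad", image_hw, "model exposes no bias gradients")
    input_grad, bias_maps = model.full_gradients(image, class_index)
    total = np.zeros(image_hw)
    total += _postprocess_term(np.abs(input_grad * image).sum(axis=2), image_hw)
    for bm in bias_maps:
        for ch in range(bm.shape[0]):
            total += _postprocess_term(np.abs(bm[ch]), image_hw)
    return _finalize("fullgrad", total, image_hw)


def _postprocess_term(term: np.ndarray, image_hw: tuple[int, int]) -> np.ndarray:
    up = upsample_bilinear(SaliencyMap(term), *image_hw)
    return normalize_unit(up).values


# ---------------------------------------------------------------------------
# RandomCAM
# ---------------------------------------------------------------------------


def random_cam(h: int, w: int, seed: int) -> CamResult:
    """Control map: i.i.d. uniform values on [-1, 1], then normalized."""
    if h <= 0 or w <= 0:
        raise ParameterError(f"dims must be positive, got ({h}, {w})")
    rng = np.random.default_rng(seed)
    raw = rng.uniform(-1.0, 1.0, size=(h, w))
    return CamResult(
        method="randomcam", map=normalize_unit(SaliencyMap(raw)), valid=True
    )


# ---------------------------------------------------------------------------
# uniform entry point
# ---------------------------------------------------------------------------


def compute_cam(
    method: str,
    model: ModelAdapter,
    image: np.ndarray,
    layer: str | None = None,
    class_index: int | None = None,
    seed: int = 0,
    score_softmax: bool = True,
) -> CamResult:
    """Compute any registered CAM method by name.

    ``layer`` defaults to the model's last capturable (convolutional)
    layer; ``class_index`` defaults to the model's argmax prediction on the
    unperturbed image.  ``seed`` only affects ``randomcam``.
    """
    if method not in CAM_METHODS:
        raise ParameterError(
            f"unknown CAM method {method!r}; available: {', '.join(CAM_METHODS)}"
        )
    image = np.asarray(image, dtype=np.float64)
    if method == "randomcam":
        return random_cam(image.shape[0], image.shape[1], seed)
    if method == "fullgrad":
        return fullgrad_map(model, image, class_index)
    if method in _PERTURBATION:
        return perturbation_cam(
            method, model, image, layer, class_index, score_softmax=score_softmax
        )
    if method in _EIGEN:
        layer, class_index = _resolve(model, image, layer, class_index)
        bundle = model.capture(image, layer, class_index)
        return eigen_cam(method, bundle, image.shape[:2])
    return assemble_cam(method, model, image, layer, class_index)


def _resolve(
    model: ModelAdapter,
    image: np.ndarray,
    layer: str | None,
    class_index: int | None,
) -> tuple[str, int]:
    if image.ndim != 3:
        raise InputError(f"image must be (H, W, C), got shape {image.shape}")
    if layer is None:
        layer = model.layer_names[-1]
    elif layer not in model.layer_names:
        raise ParameterError(
            f"unknown layer {layer!r}; capturable layers: {model.layer_names}"
        )
    if class_index is None:
        class_index = int(np.argmax(model.logits(image)))
    elif not (0 <= class_index < model.class_count):
        raise ParameterError(f"class index {class_index} out of range")
    return layer, class_index
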