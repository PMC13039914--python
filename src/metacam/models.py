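"""Model adapter: the minimal contract a classifier must satisfy.

CAM computation and ROAD evaluation never touch a network directly; they go
through :class:`ModelAdapter`, which exposes class scores (logits), softmax
confidences, and activation/gradient capture at named layers.  This keeps
the toolkit independent of any particular deep-learning framework: any
object implementing the protocol works.

The package ships one concrete adapter, :class:`TinyConvNet` — a small
convolutional classifier written directly in numpy (im2col convolutions,
hand-derived backward pass).  It serves as the desk-scale stand-in for
large pre-trained CNNs: fast to train on the synthetic fixture task, fully
deterministic, and exposing everything the CAM family needs (per-layer
activations, elementwise gradients, channel ablation, bias gradients for
FullGrad).

Images are ``(H, W, C)`` float arrays in ``[0, 1]`` throughout; the batch
dimension is an adapter-internal detail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .errors import CaptureError, InputError, ParameterError

__all__ = [
    "ActivationBundle",
    "ModelAdapter",
    "TinyConvNet",
    "predict_confidence",
    "softmax",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ActivationBundle:
    """Feature maps and matching gradients at one layer for one (image, class).

    ``feature_maps``: ``(K, h, w)`` activations (post-ReLU) at layer
    resolution; ``gradients``: ``(K, h, w)`` gradients of the target-class
    logit with respect to those activations.  Shapes match exactly and all
    entries are finite.
    """

    feature_maps: np.ndarray
    gradients: np.ndarray
    class_index: int

    def __post_init__(self):
        if self.feature_maps.shape != self.gradients.shape:
            raise CaptureError(
                "feature maps and gradients must share shape, got "
                f"{self.feature_maps.shape} vs {self.gradients.shape}"
            )
        if not (
            np.isfinite(self.feature_maps).all()
            and np.isfinite(self.gradients).all()
        ):
            raise CaptureError("non-finite values in captured activations/gradients")


@runtime_checkable
class ModelAdapter(Protocol):
    """Contract any classifier must satisfy for CAM / ROAD computation."""

    class_count: int
    layer_names: tuple[str, ...]
    input_shape: tuple[int, int, int]  # (H, W, C)

    def logits(self, image: np.ndarray) -> np.ndarray:
        """Raw class scores for one image, shape ``(class_count,)``."""
        ...

    def capture(
        self, image: np.ndarray, layer_name: str, class_index: int
    ) -> ActivationBundle:
        """Activations at ``layer_name`` and gradients of ``class_index``'s logit."""
        ...


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max()
    e = np.exp(z)
    return e / e.sum()


def predict_confidence(model: ModelAdapter, image: np.ndarray, class_index: int) -> float:
    """Softmax probability of ``class_index`` for one image.

    This is the "confidence" used by ROAD: bounded in ``[0, 1]``, so the
    combined ROAD score is scale-stable across models.
    """
    if not (0 <= class_index < model.class_count):
        raise ParameterError(
            f"class index {class_index} out of range [0, {model.class_count})"
        )
    _check_image(model, image)
    return float(softmax(model.logits(image))[class_index])


def _check_image(model: ModelAdapter, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.shape != model.input_shape:
        raise InputError(
            f"image shape {image.shape} does not match model input spec "
            f"{model.input_shape}"
        )


# ---------------------------------------------------------------------------
# numpy CNN
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray) -> np.ndarray:
    """3x3/pad-1 patch matrix: (N, C, H, W) -> (N, C*9, H*W)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (N, C, H, W, 3, 3) -> (N, C, 3, 3, H, W) -> (N, C*9, H*W)
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, c * 9, h * w
    )


def _col2im(cols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    n, c, h, w = shape
    xp = np.zeros((n, c, h + 2, w + 2))
    cols = cols.reshape(n, c, 3, 3, h, w)
    for di in range(3):
        for dj in range(3):
            xp[:, :, di : di + h, dj : dj + w] += cols[:, :, di, dj]
    return xp[:, :, 1 : 1 + h, 1 : 1 + w]


class _Conv3x3:
    """3x3 same-padding convolution with bias (stride 1)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * 9))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        n, c, h, w = x.shape
        cols = _im2col(x)
        out = np.einsum("ok,nkp->nop", self.W, cols) + self.b[None, :, None]
        return out.reshape(n, -1, h, w), {"cols": cols, "x_shape": x.shape}

    def backward(self, dout: np.ndarray, cache: dict, accumulate: bool = False):
        n, o, h, w = dout.shape
        dflat = dout.reshape(n, o, h * w)
        dW = np.einsum("nop,nkp->ok", dflat, cache["cols"])
        db = dflat.sum(axis=(0, 2))
        if accumulate:
            self.dW, self.db = dW, db
        dcols = np.einsum("ok,nop->nkp", self.W, dflat)
        return _col2im(dcols, cache["x_shape"])


class _Linear:
    def __init__(self, k_in: int, k_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(1.0 / k_in), size=(k_out, k_in))
        self.b = np.zeros(k_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray, x: np.ndarray, accumulate: bool = False):
        if accumulate:
            self.dW = dout.T @ x
            self.db = dout.sum(axis=0)
        return dout @ self.W


def _avgpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _avgpool2_back(d: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(d, 2, axis=2), 2, axis=3) / 4.0


class TinyConvNet:
    """Small convolutional classifier implementing :class:`ModelAdapter`.

    Architecture (for a ``size x size`` single- or three-channel input)::

        conv1 (3x3, C->8)  ReLU  avgpool/2
        conv2 (3x3, 8->16) ReLU  avgpool/2
        conv3 (3x3,16->16) ReLU
        global average pool -> linear -> logits

    The spatially pooled (GAP) head is the classic CAM-friendly
    architecture: channels become class-selective, so gradient-averaged
    weightings behave the way they do on large image classifiers.  (It
    also means the classification task must be channel-codable — see the
    shape-based fixture task.)  About 3.6k parameters for a grayscale
    4-class input.  The capturable
    layers are ``conv1``/``conv2``/``conv3``; captured feature maps are the
    post-ReLU activations of the named block, matching the usual CAM
    convention of hooking a layer's output.  All computation is double
    precision and deterministic (no dropout, no batch statistics), so
    capture is a pure function of (model, image, layer, class).
    """

    layer_names: tuple[str, ...] = ("conv1", "conv2", "conv3")

    def __init__(
        self,
        image_size: int = 64,
        in_channels: int = 1,
        n_classes: int = 4,
        seed: int = 0,
        channels: tuple[int, int, int] = (8, 16, 16),
    ):
        if image_size % 4 != 0 or image_size < 8:
            raise ParameterError("image_size must be a multiple of 4, >= 8")
        if n_classes < 2:
            raise ParameterError("need at least 2 classes")
        rng = np.random.default_rng(seed)
        c1, c2, c3 = channels
        self.conv1 = _Conv3x3(in_channels, c1, rng)
        self.conv2 = _Conv3x3(c1, c2, rng)
        self.conv3 = _Conv3x3(c2, c3, rng)
        self.fc = _Linear(c3, n_classes, rng)
        self.class_count = n_classes
        self.input_shape = (image_size, image_size, in_channels)
        self._meta = dict(
            image_size=image_size,
            in_channels=in_channels,
            n_classes=n_classes,
            channels=list(channels),
        )

    # -- forward -----------------------------------------------------------

    def _to_batch(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.float64)
        if image.shape != self.input_shape:
            raise InputError(
                f"image shape {image.shape} != input spec {self.input_shape}"
            )
        return image.transpose(2, 0, 1)[None]  # (1, C, H, W)

    def _forward(self, x: np.ndarray, ablate: tuple[str, int] | None = None) -> dict:
        """Full forward pass on a batch; returns every intermediate.

        ``ablate=(layer, k)`` zeroes channel ``k`` of the named layer's
        post-ReLU activations before the rest of the network runs
        (AblationCAM support).
        """
        cache: dict = {}

        def post(name, a):
            if ablate is not None and ablate[0] == name:
                a = a.copy()
                a[:, ablate[1]] = 0.0
            cache["a_" + name] = a
            return a

        z1, cache["cv1"] = self.conv1.forward(x)
        a1 = post("conv1", np.maximum(z1, 0.0))
        p1 = _avgpool2(a1)
        z2, cache["cv2"] = self.conv2.forward(p1)
        a2 = post("conv2", np.maximum(z2, 0.0))
        p2 = _avgpool2(a2)
        z3, cache["cv3"] = self.conv3.forward(p2)
        a3 = post("conv3", np.maximum(z3, 0.0))
        g = a3.mean(axis=(2, 3))
        cache.update(x=x, z1=z1, z2=z2, z3=z3, p1=p1, p2=p2, g=g)
        cache["logits"] = self.fc.forward(g)
        return cache

    def _backward(self, dlogits: np.ndarray, cache: dict, accumulate: bool = False) -> dict:
        """Backward from d(objective)/d(logits); returns all gradients."""
        grads: dict = {}
        dg = self.fc.backward(dlogits, cache["g"], accumulate)
        n3, k3, h3, w3 = cache["a_conv3"].shape
        da3 = np.broadcast_to(
            dg[:, :, None, None] / (h3 * w3), (n3, k3, h3, w3)
        ).copy()
        grads["a_conv3"] = da3
        dz3 = da3 * (cache["z3"] > 0)
        grads["z3"] = dz3
        dp2 = self.conv3.backward(dz3, cache["cv3"], accumulate)
        da2 = _avgpool2_back(dp2)
        grads["a_conv2"] = da2
        dz2 = da2 * (cache["z2"] > 0)
        grads["z2"] = dz2
        dp1 = self.conv2.backward(dz2, cache["cv2"], accumulate)
        da1 = _avgpool2_back(dp1)
        grads["a_conv1"] = da1
        dz1 = da1 * (cache["z1"] > 0)
        grads["z1"] = dz1
        grads["x"] = self.conv1.backward(dz1, cache["cv1"], accumulate)
        return grads

    # -- adapter contract ---------------------------------------------------

    def logits(self, image: np.ndarray) -> np.ndarray:
        return self._forward(self._to_batch(image))["logits"][0]

    def logits_batch(self, images: np.ndarray) -> np.ndarray:
        """Logits for a ``(N, H, W, C)`` batch (training convenience)."""
        x = np.asarray(images, dtype=np.float64).transpose(0, 3, 1, 2)
        return self._forward(x)["logits"]

    def capture(self, image: np.ndarray, layer_name: str, class_index: int) -> ActivationBundle:
        if layer_name not in self.layer_names:
            raise ParameterError(
                f"unknown layer {layer_name!r}; capturable layers: {self.layer_names}"
            )
        if not (0 <= class_index < self.class_count):
            raise ParameterError(f"class index {class_index} out of range")
        cache = self._forward(self._to_batch(image))
        onehot = np.zeros((1, self.class_count))
        onehot[0, class_index] = 1.0
        grads = self._backward(onehot, cache)
        return ActivationBundle(
            feature_maps=cache["a_" + layer_name][0].copy(),
            gradients=grads["a_" + layer_name][0].copy(),
            class_index=class_index,
        )

    # -- extended contract (AblationCAM, FullGrad) --------------------------

    def logits_with_ablation(self, image: np.ndarray, layer_name: str, channel: int) -> np.ndarray:
        if layer_name not in self.layer_names:
            raise ParameterError(f"unknown layer {layer_name!r}")
        return self._forward(self._to_batch(image), ablate=(layer_name, channel))[
            "logits"
        ][0]

    def full_gradients(self, image: np.ndarray, class_index: int):
        """Input gradient plus per-layer bias-gradient maps (FullGrad terms).

        Returns ``(input_grad (H, W, C), [bias_map_1, bias_map_2, bias_map_3])``
        where each bias map is ``(K, h, w)``: the gradient of the class logit
        with respect to the layer's pre-activation, times that channel's bias.
        The final linear bias is spatially constant and carries no saliency,
        so it is omitted.
        """
        cache = self._forward(self._to_batch(image))
        onehot = np.zeros((1, self.class_count))
        onehot[0, class_index] = 1.0
        grads = self._backward(onehot, cache)
        bias_maps = [
            grads["z1"][0] * self.conv1.b[:, None, None],
            grads["z2"][0] * self.conv2.b[:, None, None],
            grads["z3"][0] * self.conv3.b[:, None, None],
        ]
        input_grad = grads["x"][0].transpose(1, 2, 0)
        return input_grad, bias_maps

    # -- training support ---------------------------------------------------

    def loss_and_grads(self, images: np.ndarray, labels: np.ndarray) -> float:
        """Mean cross-entropy on a batch; leaves parameter grads on the layers.

        ``labels`` may be integer class indices ``(N,)`` or target
        distributions ``(N, class_count)`` (soft labels).
        """
        x = np.asarray(images, dtype=np.float64).transpose(0, 3, 1, 2)
        cache = self._forward(x)
        logits = cache["logits"]
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        labels = np.asarray(labels)
        n = len(labels)
        if labels.ndim == 1:
            targets = np.zeros_like(p)
            targets[np.arange(n), labels] = 1.0
        else:
            targets = labels.astype(np.float64)
        loss = -(targets * np.log(p + 1e-12)).sum(axis=1).mean()
        dlogits = p - targets
        self._backward(dlogits / n, cache, accumulate=True)
        return float(loss)

    def parameters(self):
        for layer in (self.conv1, self.conv2, self.conv3, self.fc):
            yield layer

    def num_parameters(self) -> int:
        return sum(l.W.size + l.b.size for l in self.parameters())


def save_model(model: TinyConvNet, path) -> None:
    """Serialize a :class:`TinyConvNet` to a ``.npz`` archive."""
    arrays = {}
    for i, layer in enumerate(model.parameters()):
        arrays[f"W{i}"] = layer.W
        arrays[f"b{i}"] = layer.b
    np.savez(path, meta=json.dumps(model._meta), **arrays)


def load_model(path) -> TinyConvNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        model = TinyConvNet(
            image_size=meta["image_size"],
            in_channels=meta["in_channels"],
            n_classes=meta["n_classes"],
            channels=tuple(meta["channels"]),
        )
        for i, layer in enumerate(model.parameters()):
            layer.W = data[f"W{i}"]
            layer.b = data[f"b{i}"]
    return model
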