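"""Synthetic planted-saliency fixtures: scenes, CAM stacks, and a trainable model.

Everything needed to exercise the toolkit end-to-end without downloading
data or weights:

* :func:`gen_scene` draws an image with one bright disk glyph over a
  textured noise background.  The class label is the glyph's *interior
  texture* (solid, horizontal stripes, vertical stripes, dot lattice),
  placed at a random position — a local, channel-codable class signal, so
  a spatially pooled classifier learns texture-selective feature channels
  the way large image classifiers do, and gradient-based CAM weightings
  behave classically.  The glyph's support is the exact ground-truth
  saliency mask.  Optionally a second glyph of a *different* class (a
  decoy) is planted disjointly: the two-subject situation where a
  non-discriminative explanation method may highlight the wrong subject.
* :func:`gen_cam_stack` fabricates component saliency maps of controlled
  fidelity around a scene: blurred truth mask plus noise, a pure-noise map
  (fidelity 0), or an "incorrect-subject" map built from the decoy mask.
* :func:`train_tiny_model` trains the numpy CNN on generated scenes to
  >= 90% held-out accuracy in well under two minutes on one CPU.

Every output is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import FixtureError, ParameterError
from .models import TinyConvNet
from .saliency import SaliencyMap, normalize_unit

__all__ = [
    "PlantedScene",
    "SyntheticCamSpec",
    "gen_scene",
    "gen_cam_stack",
    "train_tiny_model",
]


@dataclass(frozen=True)
class PlantedScene:
    """Synthetic image with exact ground-truth saliency.

    ``image``: ``(H, W, 1)`` float in [0, 1]; ``class_label``: texture
    index of the subject glyph (0=diagonal stripes, 1=horizontal stripes, 2=vertical
    stripes, 3=dot lattice); ``truth_mask``: binary subject support;
    ``decoy_mask``/``decoy_label``: the other-class glyph, if planted.
    Truth and decoy supports are disjoint.
    """

    image: np.ndarray
    class_label: int
    truth_mask: np.ndarray
    decoy_mask: np.ndarray | None = None
    decoy_label: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class SyntheticCamSpec:
    """Controller for one fabricated component map.

    ``fidelity`` in [0, 1] sets how strongly the map tracks the (blurred)
    target mask; ``noise_level >= 0`` scales an independent smooth noise
    field; ``targets_decoy`` points the map at the decoy glyph instead of
    the true subject.  ``fidelity=1, noise_level=0`` gives a map
    proportional to the blurred truth mask; ``fidelity=0, noise_level=1``
    gives a pure random map.
    """

    fidelity: float = 1.0
    noise_level: float = 0.0
    targets_decoy: bool = False

    def __post_init__(self):
        if not (0 <= self.fidelity <= 1):
            raise ParameterError(f"fidelity must be in [0, 1], got {self.fidelity}")
        if self.noise_level < 0:
            raise ParameterError("noise_level must be nonnegative")


def _background(rng: np.random.Generator, size: int) -> np.ndarray:
    """Textured background: smoothed noise around 0.25, low contrast so the
    planted subject is the dominant class evidence (the premise that makes
    the glyph support a ground-truth saliency mask)."""
    bg = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=2.0)
    bg = 0.25 + 0.07 * bg / max(bg.std(), 1e-12)
    return np.clip(bg, 0.05, 0.45)[:, :, None]


def _soft(x: np.ndarray, width: float = 1.5) -> np.ndarray:
    """Soft step: 1 where x >> 0, 0 where x << 0, linear ramp of ~width px."""
    return np.clip(x / width + 0.5, 0.0, 1.0)


def _glyph_arrays(
    label: int, cy: float, cx: float, radius: float, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Support profile and interior texture of the class's glyph.

    Every class shares the same soft-edged disk silhouette; the class is
    coded by the interior texture (period-4 patterns), so the signal a
    classifier must learn is local and channel-codable while the subject's
    support — the ground-truth saliency mask — is identical across classes.
    Returns ``(profile, texture)``, both ``(size, size)`` in [0, 1].
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    profile = _soft(radius - dist)
    # every class is a positive-evidence texture: a smooth (e.g. imputed)
    # patch supports none of them, so removing a glyph removes its class
    if label == 0:  # diagonal stripes
        texture = 0.5 + 0.5 * np.cos(2.0 * np.pi * (dy + dx) / 5.66)
    elif label == 1:  # horizontal stripes
        texture = 0.5 + 0.5 * np.cos(2.0 * np.pi * dy / 4.0)
    elif label == 2:  # vertical stripes
        texture = 0.5 + 0.5 * np.cos(2.0 * np.pi * dx / 4.0)
    elif label == 3:  # dot lattice
        texture = 0.5 + 0.5 * np.cos(2.0 * np.pi * dy / 4.0) * np.cos(
            2.0 * np.pi * dx / 4.0
        )
    else:
        raise ParameterError(f"no glyph texture for label {label}")
    return profile, texture


def _plant_glyph(
    image: np.ndarray,
    label: int,
    rng: np.random.Generator,
    avoid: np.ndarray | None = None,
) -> np.ndarray:
    """Draw a bright glyph of the label's shape at a random free position.

    ``avoid``: existing mask the new glyph must not touch (2 px clearance).
    Returns the new glyph's binary mask.
    """
    size = image.shape[0]
    if size / 7.0 + 2 >= size - (size / 7.0 + 2):
        raise ParameterError(f"size {size} too small to place a glyph")
    for _ in range(200):
        radius = rng.uniform(size / 7.0, size / 5.0)
        margin = radius + 2
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        profile, texture = _glyph_arrays(label, cy, cx, radius, size)
        mask = profile > 0.5
        if avoid is None or not (ndimage.binary_dilation(mask, iterations=2) & avoid).any():
            break
    else:
        raise ParameterError(
            f"could not place a glyph disjointly on a size-{size} image"
        )
    intensity = rng.uniform(0.85, 1.0)
    # texture oscillates between dark troughs (0.05) and bright crests
    glyph = 0.05 + (intensity - 0.05) * texture
    image[:, :, 0] = image[:, :, 0] * (1 - profile) + glyph * profile
    return mask


def gen_scene(
    seed: int,
    size: int = 64,
    n_classes: int = 4,
    with_decoy: bool = False,
) -> PlantedScene:
    """Generate one planted-saliency scene.

    The subject glyph's texture is the class label; the ground-truth mask
    records the glyph support exactly.  With ``with_decoy`` a second glyph
    of a different class (texture) is planted with 2 px clearance from the
    subject, so the two supports are disjoint.
    """
    if size < 16:
        raise ParameterError(f"size must be >= 16 to place glyphs, got {size}")
    if not (2 <= n_classes <= 4):
        raise ParameterError("the glyph-texture task supports 2-4 classes")
    rng = np.random.default_rng(seed)
    image = _background(rng, size)
    label = int(rng.integers(n_classes))
    truth_mask = _plant_glyph(image, label, rng)
    decoy_mask = None
    decoy_label = None
    if with_decoy:
        decoy_label = int((label + 1 + rng.integers(n_classes - 1)) % n_classes)
        decoy_mask = _plant_glyph(image, decoy_label, rng, avoid=truth_mask)
    np.clip(image, 0.0, 1.0, out=image)
    return PlantedScene(
        image=image,
        class_label=label,
        truth_mask=truth_mask,
        decoy_mask=decoy_mask,
        decoy_label=decoy_label,
        seed=seed,
    )


def gen_cam_stack(
    scene: PlantedScene,
    specs: list[SyntheticCamSpec],
    seed: int,
) -> list[SaliencyMap]:
    """Fabricate component saliency maps of controlled fidelity for a scene.

    Each map is ``normalize(fidelity * blur(mask) + noise_level * noise)``
    where the mask is the decoy mask when ``targets_decoy`` else the truth
    mask, and the noise field is an independent, lightly smoothed Gaussian
    field per spec (independent across specs even at equal parameters).
    """
    if not specs:
        raise ParameterError("specs must be nonempty")
    children = np.random.SeedSequence(seed).spawn(len(specs))
    h, w = scene.truth_mask.shape
    maps = []
    for spec, child in zip(specs, children):
        rng = np.random.default_rng(child)
        if spec.targets_decoy:
            if scene.decoy_mask is None:
                raise ParameterError("targets_decoy requires a scene with a decoy")
            mask = scene.decoy_mask
        else:
            mask = scene.truth_mask
        base = ndimage.gaussian_filter(mask.astype(np.float64), sigma=2.0)
        if base.max() > 0:
            base = base / base.max()
        noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=0.5)
        noise = noise / max(noise.std(), 1e-12)
        raw = spec.fidelity * base + spec.noise_level * noise
        maps.append(normalize_unit(SaliencyMap(raw)))
    return maps


def train_tiny_model(
    seed: int = 0,
    n_scenes: int = 400,
    epochs: int = 20,
    size: int = 64,
    n_classes: int = 4,
    holdout_fraction: float = 0.25,
    lr: float = 3e-3,
    batch_size: int = 8,
    min_accuracy: float = 0.9,
    early_stop_accuracy: float = 0.98,
) -> tuple[TinyConvNet, float]:
    """Train the numpy CNN on the glyph-texture task.

    Generates ``n_scenes`` decoy-free scenes plus ``n_scenes/4`` glyph-free
    background images carrying uniform soft targets — the model should be
    *uncertain* where there is no subject, which is what lets perturbation
    metrics register the removal of class evidence.  Trains with Adam on a
    train/held-out split (held-out accuracy is measured on glyph scenes
    only) and returns ``(model, holdout_accuracy)``.  Training stops early
    once held-out accuracy reaches ``early_stop_accuracy``.  Raises
    :class:`FixtureError` if held-out accuracy stays below
    ``min_accuracy`` after ``epochs`` epochs — a task/architecture
    mismatch, not a user error.  Fully deterministic under ``seed``.
    """
    if n_scenes < 50:
        raise ParameterError(f"need at least 50 scenes, got {n_scenes}")
    root = np.random.SeedSequence(seed)
    n_bg = n_scenes // 4
    all_seeds = root.generate_state(n_scenes + n_bg)  # uint32 seeds
    scenes = [
        gen_scene(int(s), size=size, n_classes=n_classes)
        for s in all_seeds[:n_scenes]
    ]
    bg_images = [
        _background(np.random.default_rng(int(s)), size)
        for s in all_seeds[n_scenes:]
    ]
    images = np.stack([s.image for s in scenes] + bg_images)
    uniform = np.full(n_classes, 1.0 / n_classes)
    targets = np.stack(
        [np.eye(n_classes)[s.class_label] for s in scenes]
        + [uniform] * n_bg
    )
    labels = np.array([s.class_label for s in scenes])

    n_hold = int(round(holdout_fraction * n_scenes))
    order_rng = np.random.default_rng(root.spawn(1)[0])
    order = order_rng.permutation(n_scenes)
    hold = order[:n_hold]
    train = np.concatenate([order[n_hold:], np.arange(n_scenes, n_scenes + n_bg)])

    model = TinyConvNet(
        image_size=size, in_channels=1, n_classes=n_classes, seed=seed
    )
    opt = _Adam(model, lr=lr)
    batch_rng = np.random.default_rng(root.spawn(2)[1])
    accuracy = 0.0
    for _ in range(epochs):
        perm = batch_rng.permutation(train)
        for start in range(0, len(perm), batch_size):
            idx = perm[start : start + batch_size]
            model.loss_and_grads(images[idx], targets[idx])
            opt.step()
        preds = np.argmax(model.logits_batch(images[hold]), axis=1)
        accuracy = float((preds == labels[hold]).mean())
        if accuracy >= early_stop_accuracy:
            break
    if accuracy < min_accuracy:
        raise FixtureError(
            f"fixture model reached only {accuracy:.3f} held-out accuracy "
            f"(< {min_accuracy}) within {epochs} epochs"
        )
    return model, accuracy


class _Adam:
    """Minimal Adam over a :class:`TinyConvNet`'s layers."""

    def __init__(self, model: TinyConvNet, lr: float = 3e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state = [
            {
                "mW": np.zeros_like(l.W),
                "vW": np.zeros_like(l.W),
                "mb": np.zeros_like(l.b),
                "vb": np.zeros_like(l.b),
            }
            for l in model.parameters()
        ]

    def step(self):
        self.t += 1
        for layer, st in zip(self.model.parameters(), self.state):
            for pname, gname, m, v in (
                ("W", "dW", "mW", "vW"),
                ("b", "db", "mb", "vb"),
            ):
                g = getattr(layer, gname)
                st[m] = self.b1 * st[m] + (1 - self.b1) * g
                st[v] = self.b2 * st[v] + (1 - self.b2) * g * g
                mhat = st[m] / (1 - self.b1**self.t)
                vhat = st[v] / (1 - self.b2**self.t)
                p = getattr(layer, pname)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
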