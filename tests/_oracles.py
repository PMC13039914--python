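"""Independent brute-force oracles used by the tests.

These deliberately re-derive results with naive loops / dense algebra so
they share no code path with the package implementations they check.
"""

import numpy as np

_OFFSETS = [
    (di, dj)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    if not (di == 0 and dj == 0)
]


def dense_impute_oracle(image, mask, direct=1.0 / 6.0, diagonal=1.0 / 12.0):
    """Noise-free neighborhood imputation via a dense loop-built solve."""
    image = np.asarray(image, dtype=float)
    squeeze = image.ndim == 2
    img = image[:, :, None] if squeeze else image
    h, w, c = img.shape
    mask = np.asarray(mask, dtype=bool)
    coords = [(r, cc) for r in range(h) for cc in range(w) if mask[r, cc]]
    index = {rc: i for i, rc in enumerate(coords)}
    n = len(coords)
    out = img.copy()
    if n == 0:
        return out[:, :, 0] if squeeze else out
    if n == h * w:
        out[:] = img.mean(axis=(0, 1))[None, None, :]
        return out[:, :, 0] if squeeze else out
    a = np.zeros((n, n))
    b = np.zeros((n, c))
    for i, (r, cc) in enumerate(coords):
        wsum = 0.0
        for di, dj in _OFFSETS:
            rr, ccc = r + di, cc + dj
            if not (0 <= rr < h and 0 <= ccc < w):
                continue
            wt = direct if (di == 0 or dj == 0) else diagonal
            wsum += wt
            if mask[rr, ccc]:
                a[i, index[(rr, ccc)]] -= wt
            else:
                b[i] += wt * img[rr, ccc]
        a[i, i] += wsum
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    for i, (r, cc) in enumerate(coords):
        out[r, cc] = sol[i]
    return out[:, :, 0] if squeeze else out


def naive_scorecam_weights(model, image, layer, class_index):
    """Per-channel masked-forward scores, softmaxed: the ScoreCAM definition."""
    bundle = model.capture(image, layer, class_index)
    a = bundle.feature_maps
    h, w = image.shape[:2]
    scores = []
    for ch in range(a.shape[0]):
        chan = a[ch]
        up = _bilinear_resize(chan, h, w)
        lo, hi = up.min(), up.max()
        m = np.zeros_like(up) if hi == lo else (up - lo) / (hi - lo)
        scores.append(model.logits(image * m[:, :, None])[class_index])
    scores = np.asarray(scores)
    e = np.exp(scores - scores.max())
    return e / e.sum()


def naive_ablation_weights(model, image, layer, class_index, eps=1e-7):
    y = float(model.logits(image)[class_index])
    denom = y if abs(y) > eps else eps
    bundle = model.capture(image, layer, class_index)
    weights = []
    for ch in range(bundle.feature_maps.shape[0]):
        y_abl = float(model.logits_with_ablation(image, layer, ch)[class_index])
        weights.append((y - y_abl) / denom)
    return np.asarray(weights)


def _bilinear_resize(arr, th, tw):
    """Align-corners bilinear resize by direct per-pixel interpolation."""
    h, w = arr.shape
    out = np.empty((th, tw))
    for i in range(th):
        y = i * (h - 1) / (th - 1) if th > 1 else 0.0
        y0 = int(np.floor(y))
        y1 = min(y0 + 1, h - 1)
        fy = y - y0
        for j in range(tw):
            x = j * (w - 1) / (tw - 1) if tw > 1 else 0.0
            x0 = int(np.floor(x))
            x1 = min(x0 + 1, w - 1)
            fx = x - x0
            out[i, j] = (
                arr[y0, x0] * (1 - fy) * (1 - fx)
                + arr[y0, x1] * (1 - fy) * fx
                + arr[y1, x0] * fy * (1 - fx)
                + arr[y1, x1] * fy * fx
            )
    return out


def iou(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = (a | b).sum()
    return (a & b).sum() / union if union else 0.0
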