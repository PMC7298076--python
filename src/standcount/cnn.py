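"""Patch-based leaf classifier and heat-map inference.

A small convolutional network classifies square RGB patches into three
classes — rapeseed leaf, weed, bare soil — and, slid over a whole plot
image, yields a per-pixel leaf-probability heat map whose local maxima mark
leaf candidates. The architecture is deliberately small: two 5x5 valid
convolutions with 12 feature maps each, each followed by 2x2 max pooling,
then one fully connected layer and a 3-way softmax. Patch sizes of 16, 24,
32, 40 and 48 pixels span the range of leaf sizes over the observed growth
stages.

The network is implemented directly on numpy (im2col convolutions,
cross-entropy loss, SGD with momentum at the default learning rate 5e-4).
Heat-map inference uses the dense dilated-convolution equivalent of the
sliding window: pooling becomes a stride-1 max with growing dilation and
the fully connected layer a dilated read of the pooled feature map, so the
dense result is numerically identical to evaluating the classifier on every
patch position independently.

The heat map is "valid"-mode: value (i, j) is the leaf probability of the
patch whose top-left corner is (i, j). ``HeatMap.offset`` = (s//2, s//2)
converts heat-map indices to plot-pixel coordinates of patch centers; no
border probabilities are fabricated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .indices import LEAF, SOIL, WEED, CLASS_NAMES

__all__ = [
    "CnnSpec",
    "PatchSample",
    "HeatMap",
    "PatchCNN",
    "UndersamplingError",
    "sample_patches",
    "train",
    "heat_map",
]

# Class-channel order of the softmax output.
CLASS_ORDER = (LEAF, WEED, SOIL)
_CLASS_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}


class UndersamplingError(ValueError):
    """Raised when a class has fewer eligible pixels than requested patches."""


@dataclass(frozen=True)
class CnnSpec:
    """Network and training hyper-parameters.

    ``patch_size`` must be a multiple of 4 and at least 16 so that two 5x5
    valid convolutions and two 2x2 poolings leave a spatial size >= 1 and
    the dense sliding-window equivalence holds exactly.
    """

    patch_size: int = 32
    kernel: int = 5
    feature_maps: int = 12
    fc_units: int = 64
    n_classes: int = 3
    learning_rate: float = 0.0005
    momentum: float = 0.9
    optimizer: str = "sgd"  # "sgd" | "adam"
    epochs: int = 10
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 16 or self.patch_size % 4 != 0:
            raise ValueError("patch_size must be >= 16 and a multiple of 4")
        if self.kernel != 5:
            raise ValueError("kernel size is fixed at 5")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        if self.pool2_out < 1:
            raise ValueError("patch too small for the architecture")

    @property
    def conv1_out(self) -> int:
        return self.patch_size - self.kernel + 1

    @property
    def pool1_out(self) -> int:
        return self.conv1_out // 2

    @property
    def conv2_out(self) -> int:
        return self.pool1_out - self.kernel + 1

    @property
    def pool2_out(self) -> int:
        return self.conv2_out // 2


@dataclass
class PatchSample:
    """One labeled training patch; pixels scaled to [0, 1]."""

    pixels: np.ndarray  # s x s x 3 float32
    label: int  # LEAF | WEED | SOIL
    source: tuple[str, int, int]  # (plot_id, center row, center col)


@dataclass
class HeatMap:
    """Valid-mode leaf-probability raster for one plot image."""

    values: np.ndarray  # (H - s + 1) x (W - s + 1) float32 in [0, 1]
    offset: tuple[int, int]  # add to heat indices to get plot pixel coords
    patch_size: int


def _he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class PatchCNN:
    """The trained classifier handle: weights plus forward/backward passes."""

    def __init__(self, spec: CnnSpec):
        self.spec = spec
        k, f = spec.kernel, spec.feature_maps
        rng = np.random.default_rng(spec.seed)
        flat = spec.pool2_out * spec.pool2_out * f
        self.params = {
            "W1": _he_init(rng, 3 * k * k, (3 * k * k, f)),
            "b1": np.zeros(f, dtype=np.float32),
            "W2": _he_init(rng, f * k * k, (f * k * k, f)),
            "b2": np.zeros(f, dtype=np.float32),
            "W3": _he_init(rng, flat, (flat, spec.fc_units)),
            "b3": np.zeros(spec.fc_units, dtype=np.float32),
            "W4": _he_init(rng, spec.fc_units, (spec.fc_units, spec.n_classes)),
            "b4": np.zeros(spec.n_classes, dtype=np.float32),
        }
        self.history: list[dict] = []

    # -- patch-mode forward / backward --------------------------------------

    def forward(self, x: np.ndarray, cache: bool = False):
        """Class probabilities for a batch of patches [B, s, s, 3]."""
        k = self.spec.kernel
        p = self.params
        c1_cols = _im2col(x, k)
        c1 = np.maximum(c1_cols @ p["W1"] + p["b1"], 0.0)
        p1, v1 = _pool2(c1)
        c2_cols = _im2col(p1, k)
        c2 = np.maximum(c2_cols @ p["W2"] + p["b2"], 0.0)
        p2, v2 = _pool2(c2)
        flat = p2.reshape(x.shape[0], -1)
        h = np.maximum(flat @ p["W3"] + p["b3"], 0.0)
        logits = h @ p["W4"] + p["b4"]
        probs = _softmax(logits)
        if not cache:
            return probs
        return probs, {
            "x": x, "c1_cols": c1_cols, "c1": c1, "p1": p1, "v1": v1,
            "c2_cols": c2_cols, "c2": c2, "p2": p2, "v2": v2,
            "flat": flat, "h": h,
        }

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def _backward(self, probs: np.ndarray, y_idx: np.ndarray, cache: dict) -> dict:
        p = self.params
        b = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(b), y_idx] -= 1.0
        dlogits /= b

        grads = {}
        grads["W4"] = cache["h"].T @ dlogits
        grads["b4"] = dlogits.sum(0)
        dh = (dlogits @ p["W4"].T) * (cache["h"] > 0)
        grads["W3"] = cache["flat"].T @ dh
        grads["b3"] = dh.sum(0)
        dflat = dh @ p["W3"].T
        dp2 = dflat.reshape(cache["p2"].shape)
        dc2 = _pool2_backward(dp2, cache["v2"], cache["p2"], cache["c2"].shape)
        dc2 *= cache["c2"] > 0
        grads["W2"] = cache["c2_cols"].reshape(-1, p["W2"].shape[0]).T @ dc2.reshape(
            -1, p["W2"].shape[1]
        )
        grads["b2"] = dc2.sum((0, 1, 2))
        dp1 = _col2im(dc2 @ p["W2"].T, cache["p1"].shape, self.spec.kernel)
        dc1 = _pool2_backward(dp1, cache["v1"], cache["p1"], cache["c1"].shape)
        dc1 *= cache["c1"] > 0
        grads["W1"] = cache["c1_cols"].reshape(-1, p["W1"].shape[0]).T @ dc1.reshape(
            -1, p["W1"].shape[1]
        )
        grads["b1"] = dc1.sum((0, 1, 2))
        return grads

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path,
            spec=json.dumps(self.spec.__dict__),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PatchCNN":
        data = np.load(path, allow_pickle=False)
        spec = CnnSpec(**json.loads(str(data["spec"])))
        model = cls(spec)
        for key in model.params:
            model.params[key] = data[key]
        return model


# -- low-level ops -----------------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """[B, H, W, C] -> [B, Ho, Wo, C*k*k] patch columns (channel-major)."""
    v = sliding_window_view(x, (k, k), axis=(1, 2))  # [B,Ho,Wo,C,k,k]
    return v.reshape(*v.shape[:3], -1)


def _col2im(dcols: np.ndarray, xshape, k: int) -> np.ndarray:
    """Scatter-add the im2col gradient back onto the input tensor."""
    b, h, w, c = xshape
    ho, wo = dcols.shape[1], dcols.shape[2]
    dv = dcols.reshape(b, ho, wo, c, k, k)
    dx = np.zeros(xshape, dtype=dcols.dtype)
    for u in range(k):
        for t in range(k):
            dx[:, u : u + ho, t : t + wo, :] += dv[:, :, :, :, u, t]
    return dx


def _pool2(x: np.ndarray):
    b, h, w, c = x.shape
    ho, wo = h // 2, w // 2
    v = x[:, : ho * 2, : wo * 2].reshape(b, ho, 2, wo, 2, c)
    return v.max(axis=(2, 4)), v


def _pool2_backward(dout, v, out, xshape):
    b, h, w, c = xshape
    ho, wo = out.shape[1], out.shape[2]
    mask = v == out[:, :, None, :, None, :]
    cnt = mask.sum(axis=(2, 4), keepdims=True)
    dv = mask * (dout[:, :, None, :, None, :] / cnt)
    dx = np.zeros(xshape, dtype=dout.dtype)
    dx[:, : ho * 2, : wo * 2] = dv.reshape(b, ho * 2, wo * 2, c)
    return dx


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# -- patch sampling ----------------------------------------------------------


def sample_patches(
    scenes,
    class_maps,
    patch_size: int,
    counts: dict[int, int],
    seed: int = 0,
) -> list[PatchSample]:
    """Sample labeled patches from (scene, class map) pairs.

    A patch's label is the class of its center pixel; patches lie fully
    inside the image; sampling is without replacement per class across all
    scenes, deterministic under ``seed``. Raises :class:`UndersamplingError`
    naming the class when a class has too few eligible center pixels.
    """
    s = patch_size
    half = s // 2
    rng = np.random.default_rng(seed)

    pools: dict[int, list[tuple[int, int, int]]] = {c: [] for c in counts}
    for si, (scene, cmap) in enumerate(zip(scenes, class_maps)):
        labels = cmap.labels if hasattr(cmap, "labels") else np.asarray(cmap)
        h, w = labels.shape
        interior = np.zeros_like(labels, dtype=bool)
        # center pixel r maps to top-left r - half; patch must fit entirely
        interior[half : h - s + half + 1, half : w - s + half + 1] = True
        for cls in counts:
            rr, cc = np.nonzero((labels == cls) & interior)
            pools[cls].extend(zip([si] * len(rr), rr.tolist(), cc.tolist()))

    samples: list[PatchSample] = []
    for cls, n in counts.items():
        if n == 0:
            continue
        pool = pools[cls]
        if len(pool) < n:
            raise UndersamplingError(
                f"class '{CLASS_NAMES.get(cls, cls)}': requested {n} patches "
                f"but only {len(pool)} eligible pixels"
            )
        idx = rng.choice(len(pool), size=n, replace=False)
        for i in idx:
            si, r, c = pool[i]
            scene = scenes[si]
            r0, c0 = r - half, c - half
            pixels = scene.image[r0 : r0 + s, c0 : c0 + s].astype(np.float32) / 255.0
            samples.append(
                PatchSample(pixels=pixels, label=cls, source=(scene.plot_id, r, c))
            )
    return samples


# -- training ----------------------------------------------------------------


def train(spec: CnnSpec, samples: list[PatchSample]) -> PatchCNN:
    """Train the patch classifier; reproducible under the spec's seed.

    Cross-entropy loss; SGD with momentum (default) or Adam at the spec's
    learning rate. The returned model's ``history`` holds one record per
    epoch: mean loss and training accuracy.
    """
    labels = {s.label for s in samples}
    if len(labels) < 2:
        raise ValueError("training requires samples from at least 2 classes")

    x = np.stack([s.pixels for s in samples]).astype(np.float32)
    y = np.array([_CLASS_INDEX[s.label] for s in samples])

    model = PatchCNN(spec)
    rng = np.random.default_rng(spec.seed + 1)
    vel = {k: np.zeros_like(v) for k, v in model.params.items()}
    if spec.optimizer == "adam":
        m1 = {k: np.zeros_like(v) for k, v in model.params.items()}
        m2 = {k: np.zeros_like(v) for k, v in model.params.items()}
        t = 0

    n = x.shape[0]
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = x[idx], y[idx]
            probs, cache = model.forward(xb, cache=True)
            eps = 1e-12
            losses.append(float(-np.mean(np.log(probs[np.arange(len(yb)), yb] + eps))))
            correct += int((probs.argmax(1) == yb).sum())
            grads = model._backward(probs, yb, cache)
            if spec.optimizer == "sgd":
                for key, g in grads.items():
                    vel[key] = spec.momentum * vel[key] - spec.learning_rate * g
                    model.params[key] += vel[key].astype(np.float32)
            else:
                t += 1
                b1, b2, eps_a = 0.9, 0.999, 1e-8
                for key, g in grads.items():
                    m1[key] = b1 * m1[key] + (1 - b1) * g
                    m2[key] = b2 * m2[key] + (1 - b2) * g * g
                    mhat = m1[key] / (1 - b1**t)
                    vhat = m2[key] / (1 - b2**t)
                    model.params[key] -= (
                        spec.learning_rate * mhat / (np.sqrt(vhat) + eps_a)
                    ).astype(np.float32)
        model.history.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "accuracy": correct / n,
            }
        )
    return model


# -- dense heat-map inference ------------------------------------------------


def _dense_conv(x: np.ndarray, w: np.ndarray, b: np.ndarray, k: int, dilation: int = 1,
                block: int = 64) -> np.ndarray:
    """Valid dilated convolution of a single [H, W, C] tensor."""
    kd = (k - 1) * dilation + 1
    v = sliding_window_view(x, (kd, kd), axis=(0, 1))[..., ::dilation, ::dilation]
    ho, wo = v.shape[0], v.shape[1]
    out = np.empty((ho, wo, w.shape[1]), dtype=np.float32)
    for i0 in range(0, ho, block):
        blk = v[i0 : i0 + block].reshape(-1, w.shape[0])
        out[i0 : i0 + block] = (blk @ w + b).reshape(-1, wo, w.shape[1])
    return out


def _stride1_pool(x: np.ndarray, dilation: int = 1) -> np.ndarray:
    d = dilation
    a = x[:-d, :-d]
    b = x[d:, :-d]
    c = x[:-d, d:]
    e = x[d:, d:]
    return np.maximum(np.maximum(a, b), np.maximum(c, e))


def heat_map(model: PatchCNN, scene, stride: int = 1) -> HeatMap:
    """Leaf-probability heat map for a plot scene (or bare image array).

    Value (i, j) equals the model's LEAF probability for the patch with
    top-left corner (i, j); shape is (H - s + 1, W - s + 1). With
    ``stride`` > 1 only every stride-th patch position is evaluated and the
    result is nearest-neighbor upsampled back to the full valid grid (a
    speed/fidelity trade-off, off by default).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    image = scene.image if hasattr(scene, "image") else np.asarray(scene)
    s = model.spec.patch_size
    if image.shape[0] < s or image.shape[1] < s:
        raise ValueError(
            f"image {image.shape[:2]} smaller than patch size {s}"
        )
    x = image.astype(np.float32) / 255.0
    k = model.spec.kernel
    p = model.params

    out1 = np.maximum(_dense_conv(x, p["W1"], p["b1"], k), 0.0)
    p1 = _stride1_pool(out1, dilation=1)
    out2 = np.maximum(_dense_conv(p1, p["W2"], p["b2"], k, dilation=2), 0.0)
    p2 = _stride1_pool(out2, dilation=2)

    n2 = model.spec.pool2_out
    d = 4 * (n2 - 1) + 1
    v = sliding_window_view(p2, (d, d), axis=(0, 1))[..., ::4, ::4]
    # [H', W', F, n2, n2] -> flatten in the patch path's (row, col, channel) order
    ho, wo = v.shape[0], v.shape[1]
    if stride > 1:
        v = v[::stride, ::stride]
    hs, ws = v.shape[0], v.shape[1]
    heat = np.empty((hs, ws), dtype=np.float32)
    for i0 in range(0, hs, 32):
        blk = v[i0 : i0 + 32].transpose(0, 1, 3, 4, 2).reshape(-1, p["W3"].shape[0])
        h = np.maximum(blk @ p["W3"] + p["b3"], 0.0)
        probs = _softmax(h @ p["W4"] + p["b4"])
        heat[i0 : i0 + 32] = probs[:, _CLASS_INDEX[LEAF]].reshape(-1, v.shape[1])
    if stride > 1:
        heat = np.repeat(np.repeat(heat, stride, axis=0), stride, axis=1)[:ho, :wo]
    return HeatMap(values=heat, offset=(s // 2, s // 2), patch_size=s)
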