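"""Minimal CPU neural-network engine used by the detection and enhancement models.

Implements the small set of building blocks the scanning pipeline needs —
im2col-based 2-D convolutions (stride 1 or 2, 'same' padding), ReLU, nearest
upsampling, average pooling, global average pooling, linear layers — together
with manual backpropagation, an Adam optimizer with cosine-annealed learning
rate, and the concrete architectures: a small patch classifier, an
encoder/decoder (U-Net style) image-to-image network with an optional 2x
upsampling head, a five-convolution discriminator, and frozen seeded
random-filter feature extractors for perceptual and FID-style distances.

Arrays are NCHW float32 by default (float64 supported for gradient checks).
No autograd: networks wire their own forward/backward explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ReLU",
    "Upsample2x",
    "AvgPool2x",
    "GlobalAvgPool",
    "Linear",
    "Adam",
    "cosine_lr",
    "SmallCNN",
    "UNet",
    "Discriminator",
    "RandomFeatureExtractor",
    "softmax_cross_entropy",
    "l1_loss",
    "mse_loss",
    "masked_mse_loss",
    "bce_with_logits",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class Param:
    """A learnable tensor with its gradient accumulator."""

    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv2d:
    """3x3 (or kxk) convolution, 'same' padding, stride 1 or 2.

    With stride 2 the input height/width must be even so output dims are
    exactly halved (the pipeline only uses power-of-two tile sizes).
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.W = Param(w.astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.k, self.stride = k, stride
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s = self.k, self.stride
        p = k // 2
        if s == 2 and (h % 2 or w % 2):
            raise ValueError("stride-2 conv requires even input dims")
        ho, wo = (h + s - 1) // s, (w + s - 1) // s
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
        colmat = cols.reshape(n, c * k * k, ho * wo)
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)
        y = np.einsum("oc,ncp->nop", wmat, colmat, optimize=True)
        y += self.b.value[None, :, None]
        if train:
            self._cache = (x.shape, colmat)
        return y.reshape(n, -1, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (n, c, h, w), colmat = self._cache
        k, s = self.k, self.stride
        p = k // 2
        ho, wo = dy.shape[2], dy.shape[3]
        dymat = dy.reshape(n, dy.shape[1], -1)
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)
        self.W.grad += np.einsum("nop,ncp->oc", dymat, colmat,
                                 optimize=True).reshape(self.W.value.shape)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dcol = np.einsum("oc,nop->ncp", wmat, dymat, optimize=True)
        dcol = dcol.reshape(n, c, k, k, ho, wo)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcol[:, :, i, j]
        self._cache = None
        return dxp[:, :, p:p + h, p:p + w]


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Upsample2x:
    """Nearest-neighbour 2x upsampling."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class AvgPool2x:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.repeat(2, axis=2).repeat(2, axis=3) * 0.25


class GlobalAvgPool:
    def __init__(self) -> None:
        self._shape: tuple | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._shape).copy()


class Linear:
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in))
        self.W = Param(w.astype(dtype))
        self.b = Param(np.zeros(d_out, dtype=dtype))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


# ---------------------------------------------------------------------------
# optimizer / schedule
# ---------------------------------------------------------------------------


def cosine_lr(base_lr: float, step: int, total_steps: int) -> float:
    """Cosine annealing without warm restarts, decaying to 0 over total_steps."""
    t = min(step, total_steps) / max(total_steps, 1)
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * t))


class Adam:
    def __init__(self, params: Sequence[Param], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# losses (each returns (loss, grad wrt prediction))
# ---------------------------------------------------------------------------


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    d = probs.copy()
    d[np.arange(n), labels] -= 1.0
    return float(loss), d / n


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.abs(diff).mean()), np.sign(diff) / diff.size


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float((diff ** 2).mean()), 2.0 * diff / diff.size


def masked_mse_loss(pred: np.ndarray, target: np.ndarray,
                    mask: np.ndarray) -> tuple[float, np.ndarray]:
    """MSE evaluated only where mask==1; gradient is zero elsewhere."""
    m = mask.astype(pred.dtype)
    denom = max(float(m.sum()), 1.0)
    diff = (pred - target) * m
    return float((diff ** 2).sum() / denom), 2.0 * diff / denom


def bce_with_logits(logits: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Binary cross-entropy against a constant 0/1 target, numerically stable."""
    t = float(target)
    # loss = softplus(x) - t*x ; dloss = sigmoid(x) - t
    sp = np.logaddexp(0.0, logits)
    loss = float((sp - t * logits).mean())
    sig = 1.0 / (1.0 + np.exp(-logits))
    return loss, (sig - t) / logits.size


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------


class _Sequential:
    def __init__(self, layers: list) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class SmallCNN:
    """Compact patch classifier: 4 conv blocks, global average pool, linear head.

    Stands behind the same interface as a full residual backbone; the desk-scale
    default used throughout the tests.
    """

    def __init__(self, in_ch: int = 3, n_classes: int = 2, base: int = 8,
                 seed: int = 0, dtype=np.float32) -> None:
        rng = np.random.default_rng(seed)
        c = base
        self.body = _Sequential([
            Conv2d(in_ch, c, rng=rng, dtype=dtype), ReLU(), AvgPool2x(),
            Conv2d(c, 2 * c, rng=rng, dtype=dtype), ReLU(), AvgPool2x(),
            Conv2d(2 * c, 4 * c, rng=rng, dtype=dtype), ReLU(), AvgPool2x(),
            Conv2d(4 * c, 4 * c, rng=rng, dtype=dtype), ReLU(),
            GlobalAvgPool(),
        ])
        self.head = Linear(4 * c, n_classes, rng=rng, dtype=dtype)
        self.config = {"in_ch": in_ch, "n_classes": n_classes, "base": base, "seed": seed}

    def params(self) -> list[Param]:
        return self.body.params() + self.head.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.head.forward(self.body.forward(x, train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.body.backward(self.head.backward(dy))

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch):
            logits = self.forward(x[i:i + batch], train=False)
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)


class UNet:
    """Two-level encoder/decoder with skip connections, one in/out channel by
    default, and an optional 2x upsampling head for super-resolution.

    Layout (base width C):
      in -> C -> [skip0] -> down(2C) -> [skip1] -> down(4C)
         -> up + skip1 -> 2C -> up + skip0 -> C -> (optional 2x up) -> out
    """

    def __init__(self, in_ch: int = 1, out_ch: int = 1, base: int = 8,
                 upscale: int = 1, seed: int = 0, dtype=np.float32) -> None:
        if upscale not in (1, 2):
            raise ValueError("upscale must be 1 or 2")
        rng = np.random.default_rng(seed)
        C = base
        mk = lambda ci, co, s=1: Conv2d(ci, co, stride=s, rng=rng, dtype=dtype)
        self.enc0 = _Sequential([mk(in_ch, C), ReLU(), mk(C, C), ReLU()])
        self.down1 = _Sequential([mk(C, 2 * C, 2), ReLU(), mk(2 * C, 2 * C), ReLU()])
        self.down2 = _Sequential([mk(2 * C, 4 * C, 2), ReLU(), mk(4 * C, 4 * C), ReLU()])
        self.up1_pre = _Sequential([Upsample2x(), mk(4 * C, 2 * C), ReLU()])
        self.up1_post = _Sequential([mk(4 * C, 2 * C), ReLU()])
        self.up2_pre = _Sequential([Upsample2x(), mk(2 * C, C), ReLU()])
        self.up2_post = _Sequential([mk(2 * C, C), ReLU()])
        head: list = []
        if upscale == 2:
            head += [Upsample2x(), mk(C, C), ReLU()]
        head += [Conv2d(C, out_ch, rng=rng, dtype=dtype)]
        self.head = _Sequential(head)
        self.upscale = upscale
        self.config = {"in_ch": in_ch, "out_ch": out_ch, "base": base,
                       "upscale": upscale, "seed": seed}
        self._split: int = 0

    def params(self) -> list[Param]:
        out: list[Param] = []
        for blk in (self.enc0, self.down1, self.down2, self.up1_pre,
                    self.up1_post, self.up2_pre, self.up2_post, self.head):
            out.extend(blk.params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        a0 = self.enc0.forward(x, train)
        a1 = self.down1.forward(a0, train)
        a2 = self.down2.forward(a1, train)
        u1 = self.up1_pre.forward(a2, train)
        b1 = self.up1_post.forward(np.concatenate([u1, a1], axis=1), train)
        u2 = self.up2_pre.forward(b1, train)
        b0 = self.up2_post.forward(np.concatenate([u2, a0], axis=1), train)
        return self.head.forward(b0, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        db0 = self.head.backward(dy)
        dcat0 = self.up2_post.backward(db0)
        c = dcat0.shape[1] // 2
        du2, da0_skip = dcat0[:, :c], dcat0[:, c:]
        db1 = self.up2_pre.backward(du2)
        dcat1 = self.up1_post.backward(db1)
        c = dcat1.shape[1] // 2
        du1, da1_skip = dcat1[:, :c], dcat1[:, c:]
        da2 = self.up1_pre.backward(du1)
        da1 = self.down2.backward(da2) + da1_skip
        da0 = self.down1.backward(da1) + da0_skip
        return self.enc0.backward(da0)

    def apply(self, image: np.ndarray) -> np.ndarray:
        """Run a single 2-D image through the network (no training caches)."""
        x = image[None, None].astype(self.params()[0].value.dtype)
        return self.forward(x, train=False)[0, 0]


class Discriminator:
    """Five stride-2 convolutions (widths doubling from `base`), each followed
    by ReLU, then global average pooling and a linear layer to one logit."""

    def __init__(self, in_ch: int = 1, base: int = 8, seed: int = 0,
                 dtype=np.float32) -> None:
        rng = np.random.default_rng(seed)
        widths = [base * 2 ** i for i in range(5)]
        layers: list = []
        c_prev = in_ch
        for c in widths:
            layers += [Conv2d(c_prev, c, stride=2, rng=rng, dtype=dtype), ReLU()]
            c_prev = c
        layers += [GlobalAvgPool()]
        self.body = _Sequential(layers)
        self.head = Linear(widths[-1], 1, rng=rng, dtype=dtype)
        self.config = {"in_ch": in_ch, "base": base, "seed": seed}

    def params(self) -> list[Param]:
        return self.body.params() + self.head.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.head.forward(self.body.forward(x, train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.body.backward(self.head.backward(dy))


class RandomFeatureExtractor:
    """Frozen, seeded random-filter convolutional stack.

    Serves as the self-contained feature extractor for perceptual distances and
    Frechet-distance features when no pretrained network is available; filters
    are fixed at construction and never trained. Grayscale inputs are used
    as-is; RGB is converted by averaging channels.
    """

    def __init__(self, n_layers: int = 3, base: int = 8, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.layers: list = []
        c_prev = 1
        for i in range(n_layers):
            c = base * 2 ** i
            self.layers += [Conv2d(c_prev, c, stride=2, rng=rng), ReLU()]
            c_prev = c
        self.out_dim = c_prev
        self.config = {"n_layers": n_layers, "base": base, "seed": seed}

    @property
    def identifier(self) -> str:
        return "random-conv:" + json.dumps(self.config, sort_keys=True)

    def _prep(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float32)
        if img.ndim == 3:
            img = img.mean(axis=2)
        h, w = img.shape
        # pad to multiple of 2**n_layers so strided convs stay even-sized
        m = 2 ** (len(self.layers) // 2)
        ph, pw = (-h) % m, (-w) % m
        if ph or pw:
            img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
        return img[None, None]

    def forward_batch(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Feature maps for an NCHW single-channel batch (train=True caches
        activations so backward_input can propagate a gradient to the input;
        the filters themselves stay frozen)."""
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward_input(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def feature_map(self, image: np.ndarray) -> np.ndarray:
        x = self._prep(image)
        for layer in self.layers:
            x = layer.forward(x, train=False)
        return x[0]

    def feature_vector(self, image: np.ndarray) -> np.ndarray:
        return self.feature_map(image).mean(axis=(1, 2))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_ARCHS: dict[str, Callable] = {
    "SmallCNN": SmallCNN,
    "UNet": UNet,
    "Discriminator": Discriminator,
}


def save_checkpoint(path, model, extra: dict | None = None) -> None:
    """Save weights + architecture config (npz with an embedded JSON header)."""
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    meta = {"arch": type(model).__name__, "config": model.config,
            "extra": extra or {}}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[object, dict]:
    """Reconstruct a model from a checkpoint; returns (model, extra)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = _ARCHS[meta["arch"]](**meta["config"])
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
    return model, meta["extra"]
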