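"""Self-supervised blind-spot denoising for laser-scanning images.

Training never sees a clean image: random dropout with a small rate p zeroes
("blinds") a sparse set of pixels of each noisy input, the network predicts
the missing values from their surroundings, and the loss is evaluated only at
the blind-spot locations — an identity mapping therefore cannot minimise it,
while zero-mean noise cannot be predicted from neighbouring pixels, so the
minimiser approaches the clean signal.

At inference, k independent dropout passes are run on the input; each pass
keeps only the predictions at its own blind spots, and the k outputs are
averaged per pixel. With k = (1/p) * 64 the probability that a pixel is never
blinded, (1 - p)^k, is negligible; any such pixel falls back to its input
value and is counted in the returned info.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "BlindSpotBatch",
    "make_blind_spots",
    "SSDConfig",
    "SSDModel",
    "train_ssd",
    "denoise",
]


@dataclass
class BlindSpotBatch:
    """An input with dropout-created blind spots (mask 1 = blinded)."""

    masked: np.ndarray
    mask: np.ndarray
    original: np.ndarray


def make_blind_spots(image: np.ndarray, p: float, seed: int,
                     rescale: bool = False) -> BlindSpotBatch:
    """Zero out an i.i.d. Bernoulli(p) subset of pixels (dropout semantics).

    `rescale` optionally multiplies the surviving pixels by 1/(1-p), classic
    dropout scaling; off by default since the sparse mask leaves near-original
    statistics.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("dropout rate p must be in (0, 1)")
    image = np.asarray(image)
    rng = np.random.default_rng(seed)
    mask = (rng.random(image.shape) < p).astype(image.dtype)
    masked = image * (1.0 - mask)
    if rescale:
        masked = masked / (1.0 - p)
    return BlindSpotBatch(masked.astype(image.dtype), mask, image)


@dataclass
class SSDConfig:
    """Training/inference configuration.

    p is the dropout rate (0.1 in practice); k defaults to ceil((1/p) * 64)
    stochastic passes at inference. `loss_on_all_pixels` is an ablation switch
    that removes the blind-spot restriction (and demonstrably collapses the
    model toward the identity mapping).
    """

    p: float = 0.1
    k: int | None = None
    base_width: int = 8
    crop: int = 64
    batch_size: int = 8
    steps: int = 300
    lr: float = 2e-4
    seed: int = 0
    loss_on_all_pixels: bool = False
    rescale_unmasked: bool = False

    @property
    def k_effective(self) -> int:
        return self.k if self.k is not None else int(np.ceil(64 / self.p))


@dataclass
class SSDModel:
    net: nn.UNet
    config: SSDConfig
    history: dict = field(default_factory=dict)

    def save(self, path) -> None:
        nn.save_checkpoint(path, self.net, extra={"ssd_config": self.config.__dict__})

    @staticmethod
    def load(path) -> "SSDModel":
        net, extra = nn.load_checkpoint(path)
        return SSDModel(net, SSDConfig(**extra["ssd_config"]))


def _random_crop(rng: np.random.Generator, images: list, size: int) -> np.ndarray:
    img = images[int(rng.integers(len(images)))]
    h, w = img.shape
    if h < size or w < size:
        raise ValueError("image smaller than the training crop")
    r = int(rng.integers(h - size + 1))
    c = int(rng.integers(w - size + 1))
    return img[r:r + size, c:c + size]


def train_ssd(noisy_images, config: SSDConfig | None = None) -> SSDModel:
    """Train the blind-spot denoiser on noisy images only.

    Each step draws fresh random crops and a fresh blind-spot mask; the loss is
    the mean squared error at the blind spots. The `loss_on_all_pixels`
    ablation removes the blind-spot scheme entirely — unmasked input, loss at
    every pixel — which lets the network see each pixel it must predict and
    collapses it to the identity mapping. Adam with cosine-annealed lr.
    """
    cfg = config or SSDConfig()
    images = [np.asarray(f.pixels if hasattr(f, "pixels") else f, dtype=np.float32)
              for f in noisy_images]
    if not images:
        raise ValueError("at least one noisy image is required")
    net = nn.UNet(in_ch=1, out_ch=1, base=cfg.base_width, upscale=1, seed=cfg.seed)
    if cfg.crop < 8:
        raise ValueError("crop smaller than the network receptive field")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(net.params(), lr=cfg.lr)
    history: dict = {"loss": []}
    for step in range(cfg.steps):
        crops = np.stack([_random_crop(rng, images, cfg.crop)
                          for _ in range(cfg.batch_size)])
        if cfg.loss_on_all_pixels:
            pred = net.forward(crops[:, None], train=True)
            loss, dpred = nn.mse_loss(pred, crops[:, None])
        else:
            batch = make_blind_spots(crops, cfg.p,
                                     seed=int(rng.integers(2 ** 31)),
                                     rescale=cfg.rescale_unmasked)
            pred = net.forward(batch.masked[:, None], train=True)
            loss, dpred = nn.masked_mse_loss(pred, batch.original[:, None],
                                             batch.mask[:, None])
        opt.zero_grad()
        net.backward(dpred.astype(pred.dtype))
        opt.step(lr=nn.cosine_lr(cfg.lr, step, cfg.steps))
        history["loss"].append(loss)
    return SSDModel(net, cfg, history)


def _pad_to_multiple(img: np.ndarray, m: int) -> tuple[np.ndarray, tuple]:
    h, w = img.shape
    ph, pw = (-h) % m, (-w) % m
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    return img, (h, w)


def denoise(model: SSDModel, image: np.ndarray, seed: int,
            p: float | None = None, k: int | None = None,
            return_info: bool = False):
    """k-pass stochastic blind-spot inference.

    For each pixel the output is the mean of the network's predictions over
    the passes in which that pixel was a blind spot; never-blinded pixels fall
    back to the input value. Deterministic for a fixed seed.
    """
    if model is None or model.net is None:
        raise ValueError("denoise requires a trained model")
    cfg = model.config
    p = p if p is not None else cfg.p
    k = k if k is not None else cfg.k_effective
    if (1 - p) ** k > 1e-6:
        import warnings
        warnings.warn("(1-p)^k > 1e-6: some pixels are likely never blinded",
                      stacklevel=2)
    img = np.asarray(image, dtype=np.float32)
    padded, (h, w) = _pad_to_multiple(img, 4)
    accum = np.zeros_like(padded, dtype=np.float64)
    count = np.zeros_like(padded, dtype=np.float64)
    rng = np.random.default_rng(seed)
    for _ in range(k):
        batch = make_blind_spots(padded, p, seed=int(rng.integers(2 ** 31)),
                                 rescale=cfg.rescale_unmasked)
        out = model.net.apply(batch.masked)
        accum += out * batch.mask
        count += batch.mask
    uncovered = count == 0
    result = np.divide(accum, count, out=padded.astype(np.float64),
                       where=~uncovered)
    result = np.clip(result[:h, :w], 0.0, 1.0).astype(np.float32)
    if return_info:
        return result, {"k": k, "p": p,
                        "uncovered_pixels": int(uncovered[:h, :w].sum())}
    return result
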