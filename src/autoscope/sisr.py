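"""Supervised single-image super-resolution (2x) with optional adversarial and
perceptual objectives, plus the run-time enhancement hook.

The generator is the encoder/decoder image-to-image network with a 2x
upsampling head; training pairs are fast-rate low-resolution frames against
slow-rate high-resolution frames of the same scene, so the network performs
denoising and upscaling simultaneously. The full objective is

    L = ||G(x) - y||_1 + lambda_p * ||V(G(x)) - V(y)||_2^2 + lambda_g * L_adv

where V is a frozen feature extractor (a bundled seeded random-filter stack by
default, so no pretrained weights are required) and L_adv is a non-saturating
GAN loss against a five-convolution discriminator. Setting
lambda_p = lambda_g = 0 degenerates exactly to the pure-L1 variant.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .phantom import (ScanSettings, SlidePhantom, render_shg, render_shg_clean)
from .ssd import SSDModel, denoise

__all__ = [
    "PairedLSMDataset",
    "build_pairs",
    "perceptual_distance",
    "SISRConfig",
    "SISRModel",
    "train_sisr",
    "enhance",
    "runtime_hook",
]


# ---------------------------------------------------------------------------
# paired data
# ---------------------------------------------------------------------------


@dataclass
class PairedLSMDataset:
    """Co-registered LR (fast scan) / HR (slow scan) tiles, scale factor 2.

    `clean_lr` / `clean_hr` are the simulator's noise-free references on the
    same normalised scale; they exist only for evaluation and are never used
    in training.
    """

    lr: np.ndarray  # (n, h, w)
    hr: np.ndarray  # (n, 2h, 2w)
    positions: np.ndarray  # (n, 3): x_um, y_um, z_um
    low_signal_threshold: float = 0.1
    clean_lr: np.ndarray | None = None
    clean_hr: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.hr.shape[1:] != (2 * self.lr.shape[1], 2 * self.lr.shape[2]):
            raise ValueError("HR dims must be exactly 2x the LR dims")

    def __len__(self) -> int:
        return len(self.lr)

    def subset(self, idx) -> "PairedLSMDataset":
        return PairedLSMDataset(
            self.lr[idx], self.hr[idx], self.positions[idx],
            self.low_signal_threshold,
            None if self.clean_lr is None else self.clean_lr[idx],
            None if self.clean_hr is None else self.clean_hr[idx])


def build_pairs(phantom: SlidePhantom, n_tiles: int, seed: int,
                lr_settings: ScanSettings | None = None,
                hr_settings: ScanSettings | None = None,
                low_signal_threshold: float = 0.1,
                include_clean: bool = True,
                max_attempts_factor: int = 8) -> PairedLSMDataset:
    """Render paired LR/HR tiles of fiber regions at their in-focus z.

    Each scene is rendered twice — fast-rate low-resolution and slow-rate
    high-resolution — with independent noise seeds; tiles whose mean pixel
    value is below the low-signal threshold (in either rendering) are
    excluded. Desk-scale defaults use 64 -> 128 px tiles spanning a quarter of
    the laser-scanning FOV at the fast (0.5 MHz) and slow (0.1 MHz) pixel
    rates, preserving the full scans' per-pixel sampling (0.51 / 0.255 um) so
    that models trained on these tiles transfer to full frames.
    """
    from .phantom import true_focus
    lq, hq = ScanSettings.shg_low_quality(), ScanSettings.shg_high_quality()
    sub_w = lq.fov_width_um * 64 / lq.nx  # 64 px at the standard sampling
    lr_set = lr_settings or replace(lq, fov_width_um=sub_w, fov_height_um=sub_w,
                                    nx=64, ny=64)
    hr_set = hr_settings or replace(hq, fov_width_um=sub_w, fov_height_um=sub_w,
                                    nx=128, ny=128)
    if (hr_set.nx, hr_set.ny) != (2 * lr_set.nx, 2 * lr_set.ny):
        raise ValueError("HR pixel counts must be 2x the LR pixel counts")
    rng = np.random.default_rng(seed)
    cores = [c for c in phantom.cores if len(c.fibers)]
    if not cores:
        raise ValueError("phantom has no fiber-bearing cores")
    lrs, hrs, poss, clr, chr_ = [], [], [], [], []
    attempts = 0
    while len(lrs) < n_tiles and attempts < max_attempts_factor * n_tiles:
        attempts += 1
        core = cores[int(rng.integers(len(cores)))]
        rr = core.radius * 0.7 * np.sqrt(rng.uniform())
        aa = rng.uniform(0, 2 * np.pi)
        x, y = core.cx + rr * np.cos(aa), core.cy + rr * np.sin(aa)
        z = true_focus(phantom, x, y)
        lr = render_shg(phantom, lr_set.with_z(z), x, y,
                        seed=int(rng.integers(2 ** 31)))
        hr = render_shg(phantom, hr_set.with_z(z), x, y,
                        seed=int(rng.integers(2 ** 31)))
        if lr.pixels.mean() < low_signal_threshold or \
                hr.pixels.mean() < low_signal_threshold:
            continue
        lrs.append(lr.pixels)
        hrs.append(hr.pixels)
        poss.append((x, y, z))
        if include_clean:
            clr.append(render_shg_clean(phantom, lr_set.with_z(z), x, y).pixels)
            chr_.append(render_shg_clean(phantom, hr_set.with_z(z), x, y).pixels)
    if not lrs:
        raise ValueError("no tiles passed the low-signal filter")
    return PairedLSMDataset(
        np.stack(lrs), np.stack(hrs), np.array(poss), low_signal_threshold,
        np.stack(clr) if clr else None, np.stack(chr_) if chr_ else None)


# ---------------------------------------------------------------------------
# perceptual distance
# ---------------------------------------------------------------------------


def perceptual_distance(a: np.ndarray, b: np.ndarray,
                        feature_extractor=None) -> float:
    """Mean-squared distance between frozen-extractor feature maps of two
    images. Symmetric; zero iff the feature maps coincide."""
    if np.asarray(a).shape != np.asarray(b).shape:
        raise ValueError("images must share dimensions")
    ext = feature_extractor or nn.RandomFeatureExtractor(seed=0)
    fa = ext.feature_map(a)
    fb = ext.feature_map(b)
    return float(((fa - fb) ** 2).mean())


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class SISRConfig:
    base_width: int = 8
    disc_base_width: int = 8
    lr: float = 2e-4
    batch_size: int = 4
    steps: int = 400
    crop_lr: int = 32
    seed: int = 0
    loss: str = "l1"  # pixel loss: "l1" (default) | "mse"
    val_fraction: float = 0.2
    val_every: int = 50


@dataclass
class SISRModel:
    generator: nn.UNet
    discriminator: nn.Discriminator | None
    config: SISRConfig
    lambda_p: float = 0.0
    lambda_g: float = 0.0
    extractor_id: str = ""
    history: dict = field(default_factory=dict)

    @property
    def checkpoint_hash(self) -> str:
        h = hashlib.sha1()
        for p in self.generator.params():
            h.update(np.ascontiguousarray(p.value).tobytes())
        return h.hexdigest()[:12]

    def save(self, path) -> None:
        nn.save_checkpoint(path, self.generator, extra={
            "sisr_config": self.config.__dict__,
            "lambda_p": self.lambda_p, "lambda_g": self.lambda_g,
            "extractor_id": self.extractor_id})

    @staticmethod
    def load(path) -> "SISRModel":
        net, extra = nn.load_checkpoint(path)
        return SISRModel(net, None, SISRConfig(**extra["sisr_config"]),
                         extra["lambda_p"], extra["lambda_g"],
                         extra.get("extractor_id", ""))


def _val_l1(gen: nn.UNet, lr: np.ndarray, hr: np.ndarray, limit: int = 4) -> float:
    tot = 0.0
    n = min(limit, len(lr))
    for i in range(n):
        out = gen.forward(lr[i][None, None].astype(np.float32), train=False)[0, 0]
        tot += float(np.abs(out - hr[i]).mean())
    return tot / max(n, 1)


def train_sisr(dataset: PairedLSMDataset, lambda_p: float = 0.1,
               lambda_g: float = 0.01, config: SISRConfig | None = None,
               feature_extractor=None) -> SISRModel:
    """Train the 2x generator with L1 + perceptual + adversarial objectives.

    With lambda_p = lambda_g = 0 no discriminator or extractor is built and
    the updates are exactly those of a pure pixel-loss trainer. Alternating
    updates otherwise: the discriminator sees real HR vs generated tiles each
    step; the generator receives the combined gradient. Aborts on NaN loss.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if lambda_p < 0 or lambda_g < 0:
        raise ValueError("loss weights must be >= 0")
    cfg = config or SISRConfig()
    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(cfg.val_fraction * len(dataset)))
    order = rng.permutation(len(dataset))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx = order
    train_lr = dataset.lr[train_idx].astype(np.float32)
    train_hr = dataset.hr[train_idx].astype(np.float32)
    val_lr = dataset.lr[val_idx].astype(np.float32)
    val_hr = dataset.hr[val_idx].astype(np.float32)

    gen = nn.UNet(in_ch=1, out_ch=1, base=cfg.base_width, upscale=2, seed=cfg.seed)
    disc = extractor = None
    opt_d = None
    if lambda_g > 0:
        disc = nn.Discriminator(in_ch=1, base=cfg.disc_base_width, seed=cfg.seed + 1)
        opt_d = nn.Adam(disc.params(), lr=cfg.lr)
    if lambda_p > 0:
        extractor = feature_extractor or nn.RandomFeatureExtractor(seed=0)
    opt_g = nn.Adam(gen.params(), lr=cfg.lr)
    pixel_loss = nn.l1_loss if cfg.loss == "l1" else nn.mse_loss

    history: dict = {"loss": [], "val_l1": [], "disc_acc": []}
    best_val, best_weights = np.inf, None
    c = cfg.crop_lr
    for step in range(cfg.steps):
        idx = rng.integers(len(train_lr), size=cfg.batch_size)
        lr_b = np.empty((cfg.batch_size, 1, c, c), np.float32)
        hr_b = np.empty((cfg.batch_size, 1, 2 * c, 2 * c), np.float32)
        for bi, ti in enumerate(idx):
            h, w = train_lr[ti].shape
            r = int(rng.integers(h - c + 1))
            cc = int(rng.integers(w - c + 1))
            lr_b[bi, 0] = train_lr[ti][r:r + c, cc:cc + c]
            hr_b[bi, 0] = train_hr[ti][2 * r:2 * r + 2 * c, 2 * cc:2 * cc + 2 * c]

        pred = gen.forward(lr_b, train=True)

        # discriminator update (real vs generated, generator held fixed)
        if disc is not None:
            opt_d.zero_grad()
            logits_real = disc.forward(hr_b, train=True)
            _, dreal = nn.bce_with_logits(logits_real, 1.0)
            disc.backward(dreal.astype(np.float32))
            logits_fake = disc.forward(pred, train=True)
            _, dfake = nn.bce_with_logits(logits_fake, 0.0)
            disc.backward(dfake.astype(np.float32))
            opt_d.step(lr=nn.cosine_lr(cfg.lr, step, cfg.steps))
            acc = 0.5 * (float((logits_real > 0).mean()) +
                         float((logits_fake <= 0).mean()))
            history["disc_acc"].append(acc)

        # generator update: combined gradient at the output
        loss_pix, dpred = pixel_loss(pred, hr_b)
        dpred = dpred.astype(np.float32)
        loss = loss_pix
        if extractor is not None:
            f_target = extractor.forward_batch(hr_b, train=False)
            f_pred = extractor.forward_batch(pred, train=True)
            diff = f_pred - f_target
            loss_perc = float((diff ** 2).mean())
            dpred += lambda_p * extractor.backward_input(
                (2.0 * diff / diff.size).astype(np.float32))
            loss += lambda_p * loss_perc
        if disc is not None:
            logits_g = disc.forward(pred, train=True)
            loss_adv, dlog = nn.bce_with_logits(logits_g, 1.0)  # non-saturating
            dpred += lambda_g * disc.backward(dlog.astype(np.float32))
            loss += lambda_g * loss_adv
        if not np.isfinite(loss):
            raise RuntimeError(f"NaN/Inf loss at step {step}: "
                               f"pixel={loss_pix}, history tail={history['loss'][-5:]}")
        opt_g.zero_grad()
        gen.backward(dpred)
        opt_g.step(lr=nn.cosine_lr(cfg.lr, step, cfg.steps))
        history["loss"].append(float(loss))

        if len(val_lr) and (step + 1) % cfg.val_every == 0:
            v = _val_l1(gen, val_lr, val_hr)
            history["val_l1"].append(v)
            if v < best_val:
                best_val = v
                best_weights = [p.value.copy() for p in gen.params()]
    if best_weights is not None:
        for p, wv in zip(gen.params(), best_weights):
            p.value[...] = wv
    ext_id = extractor.identifier if extractor is not None else ""
    return SISRModel(gen, disc, cfg, lambda_p, lambda_g, ext_id, history)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def enhance(model: SISRModel, lr_frame, max_tile: int = 128,
            halo: int = 24) -> np.ndarray:
    """2x-enhance a frame (single forward pass), output clipped to [0, 1].

    Inputs larger than `max_tile` are processed as overlapping tiles with a
    `halo` of real context on each side; only tile centres are kept, so the
    tiled result matches whole-image processing away from image borders.
    """
    if model is None or model.generator is None:
        raise ValueError("enhance requires a trained model")
    img = np.asarray(lr_frame.pixels if hasattr(lr_frame, "pixels") else lr_frame,
                     dtype=np.float32)
    h, w = img.shape
    gen = model.generator

    def run(block: np.ndarray) -> np.ndarray:
        bh, bw = block.shape
        ph, pw = (-bh) % 4, (-bw) % 4
        if ph or pw:
            block = np.pad(block, ((0, ph), (0, pw)), mode="reflect")
        out = gen.forward(block[None, None], train=False)[0, 0]
        return out[:2 * bh, :2 * bw]

    if max(h, w) <= max_tile:
        out = run(img)
    else:
        if max_tile <= 2 * halo:
            raise ValueError("max_tile must exceed twice the halo")
        out = np.zeros((2 * h, 2 * w), dtype=np.float32)
        step = max_tile - 2 * halo
        for r0 in range(0, h, step):
            for c0 in range(0, w, step):
                ra, rb = max(0, r0 - halo), min(h, r0 + step + halo)
                ca, cb = max(0, c0 - halo), min(w, c0 + step + halo)
                block_out = run(img[ra:rb, ca:cb])
                r1, c1 = min(r0 + step, h), min(c0 + step, w)
                out[2 * r0:2 * r1, 2 * c0:2 * c1] = block_out[
                    2 * (r0 - ra):2 * (r1 - ra), 2 * (c0 - ca):2 * (c1 - ca)]
    return np.clip(out, 0.0, 1.0)


class RuntimeHook:
    """Ordered chain of enhancement models applied to each acquired frame."""

    def __init__(self, models=(), seed: int = 0, ssd_k: int | None = None) -> None:
        self.models = list(models)
        self.metadata = []
        self._rng = np.random.default_rng(seed)
        self._ssd_k = ssd_k
        self.frame_times: list[float] = []
        for m in self.models:
            if isinstance(m, SSDModel):
                self.metadata.append({"kind": "ssd", "p": m.config.p,
                                      "k": ssd_k or m.config.k_effective})
            elif isinstance(m, SISRModel):
                self.metadata.append({"kind": "sisr",
                                      "checkpoint": m.checkpoint_hash})
            else:
                raise TypeError(f"unsupported model in hook chain: {type(m)}")

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        import time
        t0 = time.perf_counter()
        out = np.asarray(pixels)
        for m in self.models:
            if isinstance(m, SSDModel):
                out = denoise(m, out, seed=int(self._rng.integers(2 ** 31)),
                              k=self._ssd_k)
            else:
                out = enhance(m, out)
        self.frame_times.append(time.perf_counter() - t0)
        return out


def runtime_hook(models=(), seed: int = 0, ssd_k: int | None = None) -> RuntimeHook:
    """Build the per-frame processor for the acquisition workflow; an empty
    chain is the identity. Model order is explicit and preserved."""
    return RuntimeHook(models, seed=seed, ssd_k=ssd_k)
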