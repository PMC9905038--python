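"""Automatic ROI detection on the low-magnification prescan.

The overview mosaic is divided into non-overlapping patches; background
patches (mean HSB saturation < 0.15) are discarded; a small CNN classifies the
remaining patches; patch scores are averaged per tissue core for a core-level
call, and positive tiles are exported as stage positions plus rectangle
annotations for the high-magnification pass.

Training follows the supervised recipe: every patch inherits its core's label
(malignant = positive), cores are split 80/20 between training and validation
at the core level, and the classifier is optimised with Adam (lr 2e-4),
cosine-annealed, with cross-entropy loss (a binary-cross-entropy variant is
available). The desk-scale default backbone is a 4-block CNN on 64 px patches;
the backbone is configurable behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .acquisition import Annotation, Mosaic, PositionEntry, PositionList

__all__ = [
    "mean_saturation",
    "PatchDataset",
    "extract_patches",
    "split_by_core",
    "DetectorConfig",
    "DetectorModel",
    "train_detector",
    "predict_core",
    "detect_rois",
]


def mean_saturation(patch: np.ndarray) -> float:
    """Mean saturation of an RGB patch under the hue/saturation/brightness
    model: S = (max - min) / max per pixel, with S = 0 where max = 0."""
    p = np.asarray(patch, dtype=np.float64)
    if p.ndim != 3 or p.shape[2] != 3:
        raise ValueError("mean_saturation expects an (H, W, 3) RGB patch")
    mx = p.max(axis=2)
    mn = p.min(axis=2)
    s = np.divide(mx - mn, mx, out=np.zeros_like(mx), where=mx > 0)
    return float(s.mean())


@dataclass
class PatchDataset:
    """Fixed-size patches with per-patch labels and provenance."""

    patches: np.ndarray  # (n, size, size, 3) float32 in [0, 1]
    labels: np.ndarray  # (n,) int, -1 when unknown
    core_ids: np.ndarray  # (n,) int, -1 when unknown
    offsets: np.ndarray  # (n, 2) mosaic pixel offsets (row, col)
    patch_size: int

    def __len__(self) -> int:
        return len(self.patches)

    def subset(self, idx) -> "PatchDataset":
        return PatchDataset(self.patches[idx], self.labels[idx],
                            self.core_ids[idx], self.offsets[idx], self.patch_size)


_LABELS = {"benign": 0, "malignant": 1}


def extract_patches(mosaic: Mosaic, size: int = 224, sat_threshold: float = 0.15,
                    labeler=None) -> PatchDataset:
    """Non-overlapping grid tiling of the mosaic; partial edge tiles are
    dropped and patches with mean saturation below the threshold removed.

    `labeler(x_um, y_um) -> (core_id, label)` (e.g. the phantom ground truth at
    the patch centre) attaches labels; labelled extraction keeps only patches
    that fall on a core. Without a labeler, labels/core ids are -1.
    """
    img = mosaic.image
    if img.ndim != 3:
        raise ValueError("extract_patches expects an RGB mosaic")
    h, w = img.shape[:2]
    if h < size or w < size:
        raise ValueError("mosaic smaller than one patch")
    patches, labels, cores, offsets = [], [], [], []
    for r in range(0, h - size + 1, size):
        for c in range(0, w - size + 1, size):
            patch = img[r:r + size, c:c + size]
            if mean_saturation(patch) < sat_threshold:
                continue
            core_id, label = -1, -1
            if labeler is not None:
                x, y = mosaic.pixel_to_stage(r + size / 2 - 0.5, c + size / 2 - 0.5)
                cid, lab = labeler(float(x), float(y))
                if cid is None:
                    continue
                core_id, label = int(cid), _LABELS[lab]
            patches.append(patch.astype(np.float32))
            labels.append(label)
            cores.append(core_id)
            offsets.append((r, c))
    n = len(patches)
    return PatchDataset(
        np.stack(patches) if n else np.zeros((0, size, size, 3), np.float32),
        np.array(labels, dtype=int), np.array(cores, dtype=int),
        np.array(offsets, dtype=int).reshape(n, 2), size)


def split_by_core(dataset: PatchDataset, train_fraction: float = 0.8,
                  seed: int = 0) -> tuple[PatchDataset, PatchDataset]:
    """Core-level stratified split: no core straddles the two splits and each
    class keeps roughly the requested proportion."""
    rng = np.random.default_rng(seed)
    train_cores: list[int] = []
    val_cores: list[int] = []
    for label in np.unique(dataset.labels):
        cores = np.unique(dataset.core_ids[dataset.labels == label])
        if len(cores) < 2:
            raise ValueError("need >= 2 cores per class to split")
        cores = rng.permutation(cores)
        n_train = int(round(train_fraction * len(cores)))
        n_train = min(max(n_train, 1), len(cores) - 1)
        train_cores.extend(cores[:n_train])
        val_cores.extend(cores[n_train:])
    train_idx = np.isin(dataset.core_ids, train_cores)
    val_idx = np.isin(dataset.core_ids, val_cores)
    return dataset.subset(train_idx), dataset.subset(val_idx)


@dataclass
class DetectorConfig:
    base_width: int = 8
    lr: float = 2e-4
    batch_size: int = 64
    epochs: int = 30
    seed: int = 0
    loss: str = "ce"  # "ce" (2-logit softmax) | "bce" (1-logit)


@dataclass
class DetectorModel:
    """Trained patch classifier plus its input normalisation and history."""

    net: nn.SmallCNN
    mean: np.ndarray  # per-channel, from the training split
    std: np.ndarray
    config: DetectorConfig
    history: dict = field(default_factory=dict)

    def _prep(self, patches: np.ndarray) -> np.ndarray:
        x = (patches.astype(np.float32) - self.mean) / self.std
        return np.transpose(x, (0, 3, 1, 2))

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Positive-class probability per patch."""
        if len(patches) == 0:
            return np.zeros(0)
        x = self._prep(patches)
        if self.config.loss == "bce":
            out = []
            for i in range(0, len(x), 64):
                logits = self.net.forward(x[i:i + 64], train=False)
                out.append(1.0 / (1.0 + np.exp(-logits[:, 0])))
            return np.concatenate(out)
        return self.net.predict_proba(x)[:, 1]

    def save(self, path) -> None:
        nn.save_checkpoint(path, self.net, extra={
            "mean": self.mean.tolist(), "std": self.std.tolist(),
            "detector_config": self.config.__dict__})

    @staticmethod
    def load(path) -> "DetectorModel":
        net, extra = nn.load_checkpoint(path)
        return DetectorModel(net, np.array(extra["mean"], np.float32),
                             np.array(extra["std"], np.float32),
                             DetectorConfig(**extra["detector_config"]))


def _patch_accuracy(model: DetectorModel, ds: PatchDataset) -> float:
    if len(ds) == 0:
        return float("nan")
    pred = (model.predict_proba(ds.patches) >= 0.5).astype(int)
    return float((pred == ds.labels).mean())


def train_detector(train: PatchDataset, val: PatchDataset,
                   config: DetectorConfig | None = None) -> DetectorModel:
    """Train the patch classifier; returns the best-validation-accuracy
    weights. Seeded and deterministic on a fixed backend."""
    cfg = config or DetectorConfig()
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    mean = train.patches.mean(axis=(0, 1, 2)).astype(np.float32)
    std = np.maximum(train.patches.std(axis=(0, 1, 2)), 1e-3).astype(np.float32)
    n_out = 1 if cfg.loss == "bce" else 2
    net = nn.SmallCNN(in_ch=3, n_classes=n_out, base=cfg.base_width, seed=cfg.seed)
    model = DetectorModel(net, mean, std, cfg, history={"loss": [], "val_acc": []})

    x = model._prep(train.patches)
    y = train.labels.astype(int)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(net.params(), lr=cfg.lr)
    steps_per_epoch = max(1, int(np.ceil(len(x) / cfg.batch_size)))
    total_steps = cfg.epochs * steps_per_epoch
    best_acc, best_weights = -1.0, None
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        epoch_loss = 0.0
        for i in range(0, len(x), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = net.forward(x[idx], train=True)
            if cfg.loss == "bce":
                t = y[idx].astype(np.float64)
                sp = np.logaddexp(0.0, logits[:, 0])
                loss = float((sp - t * logits[:, 0]).mean())
                sig = 1.0 / (1.0 + np.exp(-logits[:, 0]))
                dlogits = ((sig - t) / len(t))[:, None]
            else:
                loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            net.backward(dlogits.astype(logits.dtype))
            opt.step(lr=nn.cosine_lr(cfg.lr, step, total_steps))
            step += 1
            epoch_loss += loss
        model.history["loss"].append(epoch_loss / steps_per_epoch)
        acc = _patch_accuracy(model, val)
        model.history["val_acc"].append(acc)
        if np.isnan(acc) or acc >= best_acc:
            best_acc = 0.0 if np.isnan(acc) else acc
            best_weights = [p.value.copy() for p in net.params()]
    if best_weights is not None:
        for p, wv in zip(net.params(), best_weights):
            p.value[...] = wv
    return model


def predict_core(model: DetectorModel, core_patches: np.ndarray) -> float:
    """Core-level score: arithmetic mean of per-patch positive-class
    probabilities. A core is called positive iff score >= 0.5 (ties positive)."""
    if len(core_patches) == 0:
        raise ValueError("predict_core requires at least one patch")
    return float(model.predict_proba(np.asarray(core_patches)).mean())


def detect_rois(model: DetectorModel, mosaic: Mosaic, patch_size: int | None = None,
                sat_threshold: float = 0.15, threshold: float = 0.5
                ) -> tuple[PositionList, list]:
    """Score the non-empty tiles of the mosaic and emit positive tiles as
    stage positions plus rectangle annotations (prescan pixel coordinates)."""
    if model is None:
        raise ValueError("detect_rois requires a trained model")
    size = patch_size or model.net.config.get("patch_size") or 64
    ds = extract_patches(mosaic, size=size, sat_threshold=sat_threshold)
    entries, annotations = [], []
    if len(ds):
        scores = model.predict_proba(ds.patches)
        for (r, c), s in zip(ds.offsets, scores):
            if s < threshold:
                continue
            x, y = mosaic.pixel_to_stage(r + size / 2 - 0.5, c + size / 2 - 0.5)
            entries.append(PositionEntry(float(x), float(y), tag=f"score={s:.3f}"))
            annotations.append(Annotation(
                np.array([[c, r], [c + size, r], [c + size, r + size], [c, r + size]],
                         dtype=float),
                label=f"detected:{s:.3f}", source="detector"))
    return PositionList(entries), annotations
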