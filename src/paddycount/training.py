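"""Target preparation, losses, and the SGD training loop.

Training follows the recipe the counting network was designed around: images
are brought to working resolution (1/4 of native by default), one random
384x384 crop is drawn per image per epoch, inputs are normalized with
training-set channel statistics, and the model is optimized with SGD
(initial learning rate 1e-2, divided by 10 every 200 epochs, 600 epochs,
batch 8). Classification mode trains count-interval logits with
cross-entropy; regression mode is the local-count ablation trained with an
l1 loss on raw patch counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nnkit as nn
from .codec import (
    DensityConfig,
    DotAnnotation,
    QuantizerSpec,
    class_map_from_count_map,
    count_map_from_density,
    density_from_dots,
    rasterize_dots,
)
from .network import PATCH_SIZE, CountingNetwork, save_checkpoint

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "NormalizationStats",
    "compute_normalization",
    "resize_image",
    "make_sample",
    "classification_loss",
    "regression_loss",
    "fit",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and sampling hyperparameters.

    Defaults are the full-scale recipe; CPU-scale runs shrink ``epochs``,
    ``crop`` and ``lr_decay_every`` together. ``momentum`` and
    ``weight_decay`` use the standard SGD values.
    """

    downsample_ratio: float = 0.25
    crop: int = 384
    batch: int = 8
    lr0: float = 1e-2
    lr_decay_factor: float = 10.0
    lr_decay_every: int = 200
    epochs: int = 600
    momentum: float = 0.9
    weight_decay: float = 1e-4
    seed: int = 0
    mode: str = "classification"
    val_every: int = 10

    def __post_init__(self):
        if self.crop % PATCH_SIZE:
            raise ValueError(f"crop must be divisible by {PATCH_SIZE}, got {self.crop}")
        if self.batch < 1:
            raise ValueError("batch must be >= 1")
        if self.mode not in ("classification", "regression"):
            raise ValueError(f"unknown mode '{self.mode}'")

    def lr_at(self, epoch: int) -> float:
        return self.lr0 / self.lr_decay_factor ** (epoch // self.lr_decay_every)


@dataclass(frozen=True)
class NormalizationStats:
    mean: tuple[float, float, float]
    std: tuple[float, float, float]


def compute_normalization(train_images) -> NormalizationStats:
    """Per-channel mean/std over all training pixels at working resolution.

    A degenerate (zero) std is replaced by 1 with a warning so normalization
    stays well defined on constant channels.
    """
    total = np.zeros(3)
    total_sq = np.zeros(3)
    n_px = 0
    for img in train_images:
        img = np.asarray(img, dtype=np.float64)
        total += img.sum(axis=(0, 1))
        total_sq += (img**2).sum(axis=(0, 1))
        n_px += img.shape[0] * img.shape[1]
    if n_px == 0:
        raise ValueError("compute_normalization needs at least one image")
    mean = total / n_px
    var = np.maximum(total_sq / n_px - mean**2, 0.0)
    std = np.sqrt(var)
    if np.any(std == 0):
        logger.warning("zero channel std in normalization stats; replaced by 1")
        std = np.where(std == 0, 1.0, std)
    return NormalizationStats(mean=tuple(mean), std=tuple(std))


def resize_image(image: np.ndarray, ratio: float) -> np.ndarray:
    """Bilinear resize of an HWC float image by a scale ratio."""
    if ratio == 1.0:
        return image
    from PIL import Image

    h, w = image.shape[:2]
    nh, nw = max(1, round(h * ratio)), max(1, round(w * ratio))
    pil = Image.fromarray((np.clip(image, 0, 1) * 255).astype(np.uint8))
    out = np.asarray(pil.resize((nw, nh), Image.BILINEAR), dtype=np.float32) / 255.0
    return out


def make_sample(
    image: np.ndarray,
    annotation: DotAnnotation,
    cfg: TrainConfig,
    stats: NormalizationStats,
    quantizer: QuantizerSpec,
    rng: np.random.Generator,
    sigma: float = 4.0,
    patch_stride: int = 8,
):
    """One training sample: a normalized random crop and its patch target.

    The image is brought to working resolution (dots rescaled identically),
    reflect-padded if smaller than the crop, and cropped at a uniformly drawn
    offset; the crop's dots become a density map (Gaussian sigma), then an
    overlapping 32/``patch_stride`` count map, then either a class map
    (classification) or the raw counts (regression). The rng fully determines
    the crop.

    Returns ``(chw, target, counts)`` where ``counts`` is the
    pre-quantization patch-count grid shared by both modes.
    """
    work = resize_image(np.asarray(image, dtype=np.float32), cfg.downsample_ratio)
    ann = annotation.scaled(cfg.downsample_ratio)
    h, w = work.shape[:2]
    pad_h, pad_w = max(0, cfg.crop - h), max(0, cfg.crop - w)
    if pad_h or pad_w:
        work = np.pad(work, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
        h, w = work.shape[:2]
    r0 = int(rng.integers(0, h - cfg.crop + 1))
    c0 = int(rng.integers(0, w - cfg.crop + 1))
    crop = work[r0 : r0 + cfg.crop, c0 : c0 + cfg.crop]
    pts = [
        (x - c0, y - r0)
        for x, y in ann.points
        if c0 <= x < c0 + cfg.crop and r0 <= y < r0 + cfg.crop
    ]
    dot_grid = rasterize_dots(
        DotAnnotation(annotation.image_id, pts), (cfg.crop, cfg.crop), scale=1.0
    )
    density = density_from_dots(dot_grid, DensityConfig(sigma=sigma))
    counts = count_map_from_density(density, PATCH_SIZE, patch_stride)
    if cfg.mode == "classification":
        target = class_map_from_count_map(counts, quantizer).values
    else:
        target = counts.values.astype(np.float32)
    mean = np.asarray(stats.mean, dtype=np.float32)
    std = np.asarray(stats.std, dtype=np.float32)
    chw = ((crop - mean) / std).transpose(2, 0, 1).astype(np.float32)
    return chw, target, counts.values


def classification_loss(pred, target, from_logits: bool = False):
    """Mean cross-entropy over aligned patch grids.

    ``pred`` is an (N, C, H, W) probability array (or a logit Tensor with
    ``from_logits=True``, the training path); ``target`` an integer class
    grid of matching spatial shape.
    """
    target = np.asarray(target)
    if from_logits:
        return nn.softmax_cross_entropy_map(pred, target)
    probs = np.asarray(pred, dtype=np.float64)
    if probs.shape[0] != target.shape[0] or probs.shape[2:] != target.shape[1:]:
        raise ValueError(f"misaligned grids: probs {probs.shape} vs target {target.shape}")
    n, _, h, w = probs.shape
    ni, hi, wi = np.ogrid[:n, :h, :w]
    picked = probs[ni, target, hi, wi]
    return float(-np.log(np.maximum(picked, 1e-300)).mean())


def regression_loss(pred, target):
    """Mean absolute difference over aligned patch grids."""
    if isinstance(pred, nn.Tensor):
        return nn.l1_loss(pred, np.asarray(target, dtype=np.float32))
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"misaligned grids: {pred.shape} vs {target.shape}")
    return float(np.abs(pred - target).mean())


def _dataset_pairs(dataset):
    pairs = []
    for item in dataset:
        if hasattr(item, "image") and hasattr(item, "annotation"):
            pairs.append((item.image, item.annotation))
        else:
            pairs.append(tuple(item))
    return pairs


def fit(
    dataset,
    model: CountingNetwork,
    cfg: TrainConfig,
    val_dataset=None,
    log_path: str | Path | None = None,
    checkpoint_dir: str | Path | None = None,
):
    """Train ``model`` on (image, annotation) pairs; returns (model, log).

    The epoch log records loss, learning rate and (when a validation split is
    given) validation MAE. Checkpoints best-by-validation-MAE, last, and every
    50 epochs when ``checkpoint_dir`` is set. A non-finite loss aborts with
    diagnostics.
    """
    pairs = _dataset_pairs(dataset)
    if not pairs:
        raise ValueError("empty training dataset")
    if cfg.mode != model.mode:
        raise ValueError(f"config mode '{cfg.mode}' != model mode '{model.mode}'")
    model.downsample_ratio = cfg.downsample_ratio
    if np.all(model.norm_mean == 0) and np.all(model.norm_std == 1):
        stats = compute_normalization(
            resize_image(np.asarray(img, dtype=np.float32), cfg.downsample_ratio)
            for img, _ in pairs
        )
        model.norm_mean = np.asarray(stats.mean, dtype=np.float32)
        model.norm_std = np.asarray(stats.std, dtype=np.float32)
    else:
        stats = NormalizationStats(mean=tuple(model.norm_mean), std=tuple(model.norm_std))
    opt = nn.SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    ss = np.random.SeedSequence(cfg.seed)
    log: list[dict] = []
    best_mae = np.inf
    ckpt = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt:
        ckpt.mkdir(parents=True, exist_ok=True)
    model.train()
    for epoch in range(cfg.epochs):
        rng = np.random.default_rng(ss.spawn(1)[0])
        order = rng.permutation(len(pairs))
        opt.lr = cfg.lr_at(epoch)
        losses = []
        t0 = time.time()
        for start in range(0, len(order), cfg.batch):
            idx = order[start : start + cfg.batch]
            xs, ts = [], []
            for i in idx:
                img, ann = pairs[i]
                x, t, _ = make_sample(
                    img, ann, cfg, stats, model.quantizer, rng,
                    sigma=model.sigma, patch_stride=model.patch_stride,
                )
                xs.append(x)
                ts.append(t)
            xb = np.stack(xs)
            tb = np.stack(ts)
            out = model.forward(xb)
            if cfg.mode == "classification":
                loss = classification_loss(out, tb, from_logits=True)
            else:
                loss = regression_loss(out, tb[:, None])
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch}: "
                    f"loss={lv}, lr={opt.lr}, batch mean={xb.mean():.4f}, std={xb.std():.4f}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(lv)
        entry = {
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "lr": opt.lr,
            "seconds": round(time.time() - t0, 3),
        }
        if val_dataset is not None and ((epoch + 1) % cfg.val_every == 0 or epoch == cfg.epochs - 1):
            from .inference import predict

            model.eval()
            errs = []
            for img, ann in _dataset_pairs(val_dataset):
                res = predict(model, img)
                errs.append(abs(res.total - len(ann)))
            model.train()
            entry["val_mae"] = float(np.mean(errs))
            if ckpt and entry["val_mae"] < best_mae:
                best_mae = entry["val_mae"]
                save_checkpoint(model, ckpt / "best.ckpt")
        log.append(entry)
        logger.info("epoch %d: loss=%.4f lr=%.2e %s", epoch, entry["loss"], opt.lr,
                    f"val_mae={entry.get('val_mae', float('nan')):.2f}" if "val_mae" in entry else "")
        if ckpt and (epoch + 1) % 50 == 0:
            save_checkpoint(model, ckpt / f"epoch_{epoch + 1:04d}.ckpt")
    model.eval()
    if ckpt:
        save_checkpoint(model, ckpt / "last.ckpt")
    if log_path:
        with open(log_path, "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    return model, log
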