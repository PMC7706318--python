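"""Whole-image prediction: pad, forward, decode classes to a count total.

The network is fully convolutional, so inference runs on the whole image at
working resolution: the input is normalized, reflect-padded on the right and
bottom to the next multiple of 32, forwarded once, and the per-patch class
argmax is dequantized to patch counts. Deredundancy averages the overlapping
patch counts into a pixel-resolution count map, padded margins are discarded,
and the total is the sum of the remaining pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .codec import (
    ClassMap,
    CountMap,
    PatchGrid,
    PixelCountMap,
    dequantize_class_map,
    deredundancy,
)
from .network import PATCH_SIZE, CountingNetwork, class_probabilities, predict_class_map
from .training import resize_image

logger = logging.getLogger(__name__)

__all__ = ["PredictionResult", "predict", "predict_batch"]


@dataclass
class PredictionResult:
    image_id: str
    total: float
    pixel_map: PixelCountMap
    class_grid: ClassMap | None


def _prepare(model: CountingNetwork, image: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Working-resolution, normalized, padded NCHW input; returns unpadded dims."""
    image = np.asarray(image, dtype=np.float32)
    if image.size == 0:
        raise ValueError("zero-size input image")
    if image.ndim == 2:
        logger.warning("grayscale input; replicating to 3 channels")
        image = np.stack([image] * 3, axis=-1)
    work = resize_image(image, model.downsample_ratio)
    h, w = work.shape[:2]
    pad_h = (-h) % PATCH_SIZE
    pad_w = (-w) % PATCH_SIZE
    if pad_h or pad_w:
        work = np.pad(work, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
    x = ((work - model.norm_mean) / model.norm_std).transpose(2, 0, 1)[None]
    return x.astype(np.float32), (h, w)


def predict(model: CountingNetwork, image: np.ndarray, image_id: str = "") -> PredictionResult:
    """Count the plants in one image (HWC float array at native resolution)."""
    x, (h, w) = _prepare(model, image)
    model.eval()
    out = model.forward(x).data[0]
    grid = PatchGrid(block=PATCH_SIZE, stride=model.patch_stride, image_shape=x.shape[2:])
    if model.mode == "classification":
        class_grid = predict_class_map(out, x.shape[2:], model.quantizer, model.patch_stride)
        counts = dequantize_class_map(class_grid)
    else:
        class_grid = None
        counts = CountMap(values=np.maximum(out[0].astype(np.float64), 0.0), grid=grid)
    pixel = deredundancy(counts)
    cropped = PixelCountMap(values=pixel.values[:h, :w])
    return PredictionResult(
        image_id=image_id, total=cropped.total(), pixel_map=cropped, class_grid=class_grid
    )


def predict_batch(model: CountingNetwork, images, image_ids=None, out_csv: str | Path | None = None):
    """Per-image predictions for a list of images; order preserving.

    A failure on one image is reported and recorded (total = NaN) without
    aborting the batch; if every image fails, an error is raised. Optionally
    writes a CSV with columns image,total,total_rounded.
    """
    images = list(images)
    if not images:
        raise ValueError("empty image list")
    if image_ids is None:
        image_ids = [f"image_{i:04d}" for i in range(len(images))]
    results: list[PredictionResult] = []
    n_failed = 0
    for img, name in zip(images, image_ids):
        try:
            results.append(predict(model, img, image_id=name))
        except Exception as exc:  # noqa: BLE001 - per-image isolation is the point
            logger.error("prediction failed for %s: %s", name, exc)
            results.append(PredictionResult(name, float("nan"), PixelCountMap(np.zeros((0, 0))), None))
            n_failed += 1
    if n_failed == len(images):
        raise RuntimeError("all images failed to predict")
    if out_csv:
        import pandas as pd

        pd.DataFrame(
            {
                "image": [r.image_id for r in results],
                "total": [r.total for r in results],
                "total_rounded": [
                    int(round(r.total)) if np.isfinite(r.total) else -1 for r in results
                ],
            }
        ).to_csv(out_csv, index=False)
    return results
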