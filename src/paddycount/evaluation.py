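"""Counting metrics: MAE, RMSE, relative MAE and R².

MAE = mean |gt - est|, RMSE = sqrt(mean (gt - est)^2), rMAE = the mean of
|est - gt| / gt as a percentage, and R² defaults to the squared Pearson
correlation of ground-truth vs estimated totals (the scatter-plot
convention); the 1 - SS_res/SS_tot definition and a no-root mean-square
variant are available by flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["MetricsReport", "compute_metrics", "evaluate"]


@dataclass(frozen=True)
class MetricsReport:
    mae: float
    rmse: float
    rmae: float  # percent; NaN when any ground truth is zero
    r2: float
    n: int

    def as_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "rmae": self.rmae, "r2": self.r2, "n": self.n}


def compute_metrics(
    gt, est, r2_definition: str = "pearson", rmse_root: bool = True
) -> MetricsReport:
    """Metric suite over paired per-image ground-truth and estimated counts."""
    gt = np.asarray(gt, dtype=np.float64)
    est = np.asarray(est, dtype=np.float64)
    if gt.shape != est.shape or gt.ndim != 1 or gt.size == 0:
        raise ValueError(f"need equal-length nonempty 1-D lists, got {gt.shape} and {est.shape}")
    err = est - gt
    mae = float(np.abs(err).mean())
    mse = float((err**2).mean())
    rmse = float(np.sqrt(mse)) if rmse_root else mse
    if np.any(gt == 0):
        logger.warning("ground-truth count of 0 present; rMAE undefined for this run")
        rmae = float("nan")
    else:
        rmae = float((np.abs(err) / gt).mean() * 100.0)
    if gt.size < 2 or np.ptp(gt) == 0 or np.ptp(est) == 0:
        r2 = float("nan")
    elif r2_definition == "pearson":
        r2 = float(np.corrcoef(gt, est)[0, 1] ** 2)
    elif r2_definition == "ss":
        r2 = float(1.0 - (err**2).sum() / ((gt - gt.mean()) ** 2).sum())
    else:
        raise ValueError(f"unknown r2 definition '{r2_definition}'")
    report = MetricsReport(mae=mae, rmse=rmse, rmae=rmae, r2=r2, n=int(gt.size))
    assert not rmse_root or report.rmse >= report.mae - 1e-12
    return report


def evaluate(model, dataset, r2_definition: str = "pearson"):
    """Run the model over an annotated dataset and score the totals.

    ``dataset`` yields objects with ``.image``/``.annotation`` or (image,
    annotation) pairs; images without an annotation are skipped with a
    warning. Returns ``(MetricsReport, per_image)`` where ``per_image`` is a
    DataFrame with columns image, gt, est, abs_err, rel_err, ready for a
    gt-vs-est scatter plot.
    """
    import pandas as pd

    from .inference import predict

    rows = []
    for i, item in enumerate(dataset):
        if hasattr(item, "image"):
            img, ann = item.image, item.annotation
        else:
            img, ann = item
        if ann is None:
            logger.warning("image %d has no annotation; excluded from evaluation", i)
            continue
        res = predict(model, img, image_id=ann.image_id or f"image_{i:04d}")
        gt = float(len(ann))
        rows.append(
            {
                "image": res.image_id,
                "gt": gt,
                "est": res.total,
                "abs_err": abs(res.total - gt),
                "rel_err": abs(res.total - gt) / gt if gt > 0 else float("nan"),
            }
        )
    if not rows:
        raise ValueError("no annotated images to evaluate")
    per_image = pd.DataFrame(rows)
    report = compute_metrics(per_image["gt"], per_image["est"], r2_definition=r2_definition)
    return report, per_image
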