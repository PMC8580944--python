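"""End-to-end prediction (field -> ellipse -> HC) and evaluation metrics.

Metrics follow the challenge conventions: DF/ADF are the signed and
absolute HC differences in millimetres (sign = prediction minus reference,
so a negative mean reads as under-estimation), HD is the classic symmetric
Hausdorff distance between densely sampled contours in millimetres, and
DSC is the Dice coefficient between filled head masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import transform as sktransform

from .ellipse import HCMeasurement, fit_ellipse, measure_ellipse, threshold_field
from .errors import FetalHCError, NoDetectionError
from .net import Detection, MaskR2CNN
from .targets import EllipseParams, ResizeTransform, resize_with_padding

__all__ = [
    "MetricsReport", "predict_field", "delineate", "delineate_image",
    "metric_df_adf", "metric_dsc", "dice_masks", "metric_hd",
    "evaluate_dataset", "rasterize_filled_ellipse",
]


@dataclass
class MetricsReport:
    """Per-image and aggregate delineation metrics."""

    per_image: pd.DataFrame           # columns: name, DF, ADF, HD, DSC
    mean: dict                        # metric -> mean over evaluated images
    sd: dict                          # metric -> standard deviation
    n_images: int
    n_missing: int                    # no-measurement records


def predict_field(image: np.ndarray, model: MaskR2CNN,
                  transform: ResizeTransform | None = None):
    """Regress the full-image distance field for the top-scoring detection.

    ``image`` is the network-resolution square image in [0, 1]. The
    detection's field patch is bilinearly resized to its box and pasted
    into a zero canvas; if a resize ``transform`` is given the canvas is
    mapped back to source-image coordinates. Values are clipped to [0, 1].
    """
    dets = model.full_forward(image)
    if not dets:
        raise NoDetectionError("no head detected above the score threshold")
    det = dets[0]
    canvas = np.zeros(image.shape, dtype=np.float32)
    x1 = int(math.floor(det.box.x1))
    y1 = int(math.floor(det.box.y1))
    x2 = int(math.ceil(det.box.x2))
    y2 = int(math.ceil(det.box.y2))
    x1, y1 = max(x1, 0), max(y1, 0)
    x2 = min(x2, image.shape[1])
    y2 = min(y2, image.shape[0])
    if x2 <= x1 or y2 <= y1:
        raise NoDetectionError("degenerate detection box")
    patch = sktransform.resize(det.field_patch, (y2 - y1, x2 - x1), order=1,
                               anti_aliasing=False, preserve_range=True)
    canvas[y1:y2, x1:x2] = np.clip(patch, 0.0, 1.0)
    if transform is not None:
        canvas = np.clip(transform.invert_field(canvas), 0.0, 1.0)
    return canvas, det


def delineate(image: np.ndarray, mm_per_px: float, model: MaskR2CNN,
              transform: ResizeTransform | None = None,
              threshold: float = 0.9) -> HCMeasurement:
    """Field regression -> threshold -> ellipse fit -> HC in millimetres.

    ``image`` is at network resolution; ellipse parameters are reported in
    the coordinates of the (inverse-transformed) field, i.e. source pixels
    when ``transform`` is given. Detection and fit failures propagate as
    :class:`FetalHCError` subclasses for the caller to record.
    """
    field, _ = predict_field(image, model, transform)
    pts = threshold_field(field, threshold)
    params = fit_ellipse(pts)
    return measure_ellipse(params, mm_per_px)


def delineate_image(image_src: np.ndarray, mm_per_px: float, model: MaskR2CNN,
                    threshold: float = 0.9) -> HCMeasurement:
    """Convenience wrapper: resize a source image to the network size with
    zero padding, then delineate in source coordinates."""
    img = np.asarray(image_src, dtype=np.float32)
    if img.max() > 1.5:
        img = img / 255.0
    net_img, tr = resize_with_padding(img, model.cfg.image_size)
    return delineate(net_img, mm_per_px, model, transform=tr,
                     threshold=threshold)


# ---------------------------------------------------------------------------
# metrics


def metric_df_adf(pred, gt) -> tuple[float, float]:
    """Signed and absolute HC difference in mm (prediction minus reference)."""
    hp = pred.hc_mm if isinstance(pred, HCMeasurement) else float(pred)
    hg = gt.hc_mm if isinstance(gt, HCMeasurement) else float(gt)
    df = hp - hg
    return df, abs(df)


def rasterize_filled_ellipse(params: EllipseParams, shape) -> np.ndarray:
    """Boolean mask of the filled ellipse on the given (h, w) canvas."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - params.cx
    dy = yy - params.cy
    ct, st = math.cos(params.theta), math.sin(params.theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / params.a) ** 2 + (v / params.b) ** 2 <= 1.0


def dice_masks(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A^B| / (|A|+|B|) between two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        raise ValueError("both masks are empty")
    return 2.0 * float(np.logical_and(a, b).sum()) / (sa + sb)


def metric_dsc(pred: EllipseParams, gt: EllipseParams, shape) -> float:
    """Dice between the filled predicted and reference head ellipses."""
    return dice_masks(rasterize_filled_ellipse(pred, shape),
                      rasterize_filled_ellipse(gt, shape))


def metric_hd(pred: EllipseParams, gt: EllipseParams, mm_per_px: float = 1.0,
              n_samples: int = 3600) -> float:
    """Symmetric Hausdorff distance between the two contours, in mm."""
    pa = pred.sample_points(n_samples)
    pb = gt.sample_points(n_samples)
    da = cKDTree(pb).query(pa, workers=1)[0].max()
    db = cKDTree(pa).query(pb, workers=1)[0].max()
    return float(max(da, db)) * mm_per_px


def evaluate_dataset(preds: dict, gts: dict, shapes: dict | None = None,
                     mm_per_px: dict | None = None) -> MetricsReport:
    """Per-image DF/ADF/HD/DSC plus mean and standard deviation.

    ``preds`` maps filename -> HCMeasurement or None (a no-measurement
    record); ``gts`` maps filename -> HCMeasurement. ``shapes`` gives the
    (h, w) canvas per image for the Dice masks (required when ellipse
    metrics are wanted). Keys of ``preds`` and ``gts`` must coincide.
    """
    if set(preds) != set(gts):
        raise KeyError("prediction/ground-truth filename sets differ")
    rows = []
    n_missing = 0
    for name in sorted(gts):
        gt = gts[name]
        pred = preds[name]
        if pred is None:
            n_missing += 1
            continue
        df, adf = metric_df_adf(pred, gt)
        hd = dsc = float("nan")
        if shapes is not None:
            mpp = gt.mm_per_px if mm_per_px is None else mm_per_px[name]
            hd = metric_hd(pred.params, gt.params, mpp)
            dsc = metric_dsc(pred.params, gt.params, shapes[name])
        rows.append({"name": name, "DF": df, "ADF": adf, "HD": hd, "DSC": dsc})
    per_image = pd.DataFrame(rows, columns=["name", "DF", "ADF", "HD", "DSC"])
    mean = {k: float(per_image[k].mean()) for k in ("DF", "ADF", "HD", "DSC")} \
        if len(per_image) else {k: float("nan") for k in ("DF", "ADF", "HD", "DSC")}
    sd = {k: float(per_image[k].std(ddof=0)) for k in ("DF", "ADF", "HD", "DSC")} \
        if len(per_image) else {k: float("nan") for k in ("DF", "ADF", "HD", "DSC")}
    return MetricsReport(per_image=per_image, mean=mean, sd=sd,
                         n_images=len(gts), n_missing=n_missing)
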