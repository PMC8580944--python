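"""Axis-aligned box utilities: IoU, delta encoding, NMS.

Boxes are numpy ``(n, 4)`` arrays ``[x1, y1, x2, y2]`` (half-open). Deltas
use the standard log-space parameterization ``(dx, dy, dw, dh)`` relative
to the anchor/proposal size.
"""

from __future__ import annotations

import numpy as np

BBOX_XFORM_CLIP = np.log(1000.0 / 16.0)


def box_area(boxes: np.ndarray) -> np.ndarray:
    return np.maximum(boxes[:, 2] - boxes[:, 0], 0) * np.maximum(
        boxes[:, 3] - boxes[:, 1], 0)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU, shape (len(a), len(b))."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.maximum(x2 - x1, 0) * np.maximum(y2 - y1, 0)
    union = box_area(a)[:, None] + box_area(b)[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def encode_deltas(boxes: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Deltas that map ``anchors`` onto ``boxes``."""
    anchors = np.asarray(anchors, dtype=np.float64)
    boxes = np.asarray(boxes, dtype=np.float64)
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    bw = boxes[:, 2] - boxes[:, 0]
    bh = boxes[:, 3] - boxes[:, 1]
    bcx = boxes[:, 0] + bw / 2
    bcy = boxes[:, 1] + bh / 2
    return np.stack([
        (bcx - acx) / aw, (bcy - acy) / ah,
        np.log(bw / aw), np.log(bh / ah),
    ], axis=1)


def decode_deltas(deltas: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    anchors = np.asarray(anchors, dtype=np.float64)
    deltas = np.asarray(deltas, dtype=np.float64)
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    cx = deltas[:, 0] * aw + acx
    cy = deltas[:, 1] * ah + acy
    w = aw * np.exp(np.minimum(deltas[:, 2], BBOX_XFORM_CLIP))
    h = ah * np.exp(np.minimum(deltas[:, 3], BBOX_XFORM_CLIP))
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def clip_boxes(boxes: np.ndarray, size: int) -> np.ndarray:
    return np.clip(boxes, 0, size)


def nms(boxes: np.ndarray, scores: np.ndarray, thresh: float,
        max_keep: int | None = None) -> np.ndarray:
    """Greedy IoU-based non-maximum suppression; returns kept indices.

    ``max_keep`` stops early once that many boxes survive.
    """
    boxes = np.asarray(boxes, dtype=np.float64)
    order = np.argsort(-scores, kind="stable")
    x1, y1, x2, y2 = boxes.T
    areas = np.maximum(x2 - x1, 0) * np.maximum(y2 - y1, 0)
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if max_keep is not None and len(keep) >= max_keep:
            break
        if order.size == 1:
            break
        rest = order[1:]
        ix1 = np.maximum(x1[i], x1[rest])
        iy1 = np.maximum(y1[i], y1[rest])
        ix2 = np.minimum(x2[i], x2[rest])
        iy2 = np.minimum(y2[i], y2[rest])
        inter = np.maximum(ix2 - ix1, 0) * np.maximum(iy2 - iy1, 0)
        union = areas[i] + areas[rest] - inter
        iou = np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)
        order = rest[iou <= thresh]
    return np.asarray(keep, dtype=np.int64)
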