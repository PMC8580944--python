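"""Shared sample container passed between IO, training and inference."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .targets import BBox, EllipseParams, ResizeTransform


@dataclass
class Sample:
    """One image with its calibration and derived regression targets.

    ``image`` and ``field`` live at network resolution (square, side
    divisible by 64); ``ellipse_net`` is the ground-truth ellipse in those
    coordinates while ``ellipse_src`` / ``mm_per_px`` refer to the original
    image so that HC in millimetres is computed on source pixels.
    """

    name: str
    image: np.ndarray          # float32 in [0, 1]
    mm_per_px: float           # physical size of a SOURCE pixel
    field: np.ndarray          # float32 distance field, same shape as image
    box: BBox                  # tight box around the field support
    ellipse_net: EllipseParams | None = None
    ellipse_src: EllipseParams | None = None
    transform: ResizeTransform | None = None
    hc_mm: float | None = None
    trimester: int | None = None
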