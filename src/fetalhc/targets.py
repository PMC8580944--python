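"""Ground-truth construction for distance-field regression.

The fetal skull is annotated as a thin elliptical contour. Training targets
are built from it in three steps: rasterize the ellipse as a thin band,
thin it to a one-pixel skeleton, and spread a Gaussian profile of standard
deviation ``r/2`` around the skeleton as a function of Euclidean distance.
The bounding-box target is the tightest axis-aligned box containing the
field's support. All coordinates are 0-based ``(row, col)`` raster order;
boxes are half-open ``[x1, x2) x [y1, y2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import morphology, transform

from .errors import ConfigError, EmptyAnnotationError

__all__ = [
    "EllipseParams",
    "FieldConfig",
    "BBox",
    "ResizeTransform",
    "rasterize_ellipse",
    "skeletonize_contour",
    "build_distance_field",
    "field_bbox",
    "resize_with_padding",
]


@dataclass(frozen=True)
class EllipseParams:
    """Ellipse in pixel coordinates: center, semi-axes, orientation.

    ``theta`` is the angle of the semi-major axis, counter-clockwise from
    the +x (column) axis, in radians. Canonical form has ``a >= b`` and
    ``theta in [0, pi)``; for circles ``theta`` is fixed at 0.
    """

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("semi-axes must be positive")

    def canonical(self) -> "EllipseParams":
        a, b, th = self.a, self.b, self.theta
        if b > a:
            a, b = b, a
            th = th + math.pi / 2
        th = th % math.pi
        if th >= math.pi:  # tiny negative angles can round up to pi
            th = 0.0
        if math.isclose(a, b, rel_tol=1e-12, abs_tol=1e-12):
            th = 0.0
        return replace(self, a=a, b=b, theta=th)

    def sample_points(self, n: int = 3600) -> np.ndarray:
        """``n`` parametric samples, returned as (n, 2) array of (x, y)."""
        t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        ct, st = np.cos(self.theta), np.sin(self.theta)
        x = self.cx + self.a * np.cos(t) * ct - self.b * np.sin(t) * st
        y = self.cy + self.a * np.cos(t) * st + self.b * np.sin(t) * ct
        return np.stack([x, y], axis=1)


@dataclass(frozen=True)
class FieldConfig:
    """Distance-field construction parameters.

    ``r`` is the band thickness in pixels; the Gaussian profile has
    ``sigma = r/2``. ``support`` selects where the field is truncated to
    zero: ``"band"`` keeps ``d <= r/2`` (a band of total thickness ``r``
    around the contour), ``"wide"`` keeps ``d <= r``.
    """

    r: float = 100.0
    support: str = "band"

    def __post_init__(self):
        if self.r < 2:
            raise ConfigError("band thickness r must be >= 2")
        if self.support not in ("band", "wide"):
            raise ConfigError("support must be 'band' or 'wide'")

    @property
    def sigma(self) -> float:
        return self.r / 2.0

    @property
    def cutoff(self) -> float:
        return self.r / 2.0 if self.support == "band" else float(self.r)


@dataclass(frozen=True)
class BBox:
    """Half-open pixel box [x1, x2) x [y1, y2), 0-based."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise ValueError("box must have positive extent")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=np.float64)


@dataclass(frozen=True)
class ResizeTransform:
    """Invertible record of the aspect-preserving resize + zero padding."""

    scale: float
    pad_right: int
    pad_bottom: int
    src_shape: tuple
    dst_shape: tuple

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map (x, y) points from source to destination coordinates."""
        return np.asarray(pts, dtype=np.float64) * self.scale

    def invert_points(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=np.float64) / self.scale

    def invert_field(self, canvas: np.ndarray) -> np.ndarray:
        """Map a field at network resolution back to source resolution."""
        h_dst = self.dst_shape[0] - self.pad_bottom
        w_dst = self.dst_shape[1] - self.pad_right
        content = canvas[:h_dst, :w_dst]
        out = transform.resize(
            content, self.src_shape, order=1, anti_aliasing=False,
            preserve_range=True, mode="edge",
        )
        return np.asarray(out, dtype=canvas.dtype if canvas.dtype.kind == "f" else np.float64)


def rasterize_ellipse(params: EllipseParams, height: int, width: int,
                      line_width: float = 2.0) -> np.ndarray:
    """Draw the ellipse contour with the given line width, clipped to canvas.

    A pixel is on iff its center lies within ``line_width/2`` of the
    continuous contour (measured against a dense parametric sampling).
    """
    if height <= 0 or width <= 0:
        raise ValueError("canvas must be positive")
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    p = params.canonical()
    # dense sampling: arc spacing well below half a pixel
    n = max(256, int(16 * p.a))
    pts = p.sample_points(n)

    half = line_width / 2.0
    x_lo = max(0, int(math.floor(pts[:, 0].min() - half - 1)))
    x_hi = min(width - 1, int(math.ceil(pts[:, 0].max() + half + 1)))
    y_lo = max(0, int(math.floor(pts[:, 1].min() - half - 1)))
    y_hi = min(height - 1, int(math.ceil(pts[:, 1].max() + half + 1)))
    mask = np.zeros((height, width), dtype=np.uint8)
    if x_lo > x_hi or y_lo > y_hi:
        raise EmptyAnnotationError("ellipse entirely outside the canvas")

    xs = np.arange(x_lo, x_hi + 1)
    ys = np.arange(y_lo, y_hi + 1)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1).astype(np.float64)
    d, _ = cKDTree(pts).query(grid, workers=1)
    on = d <= half
    if not on.any():
        raise EmptyAnnotationError("ellipse entirely outside the canvas")
    mask[gy.ravel()[on], gx.ravel()[on]] = 1
    return mask


def skeletonize_contour(mask: np.ndarray) -> np.ndarray:
    """Thin a binary contour band to a one-pixel-wide curve."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyAnnotationError("cannot skeletonize an empty mask")
    skel = morphology.skeletonize(mask)
    # guarantee one-pixel width: break any remaining 2x2 solid block
    solid = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
    for ry, rx in zip(*np.nonzero(solid)):
        skel[ry, rx] = False
    return skel.astype(np.uint8)


def build_distance_field(skel: np.ndarray, cfg: FieldConfig = FieldConfig()) -> np.ndarray:
    """Gaussian-of-distance field around a skeleton.

    ``F(p) = exp(-d(p)^2 / (2 sigma^2))`` with ``sigma = r/2`` and ``d`` the
    Euclidean distance to the nearest skeleton pixel, truncated to zero
    beyond the configured support. ``F == 1`` exactly on the skeleton.
    """
    skel = np.asarray(skel).astype(bool)
    if not skel.any():
        raise EmptyAnnotationError("cannot build a field from an empty skeleton")
    d = ndimage.distance_transform_edt(~skel)
    f = np.exp(-(d ** 2) / (2.0 * cfg.sigma ** 2))
    f[d > cfg.cutoff] = 0.0
    f[skel] = 1.0
    return f.astype(np.float32)


def field_bbox(field: np.ndarray) -> BBox:
    """Minimal half-open box containing all strictly positive pixels."""
    nz = np.nonzero(np.asarray(field) > 0)
    if nz[0].size == 0:
        raise EmptyAnnotationError("field has no positive pixels")
    y1, y2 = int(nz[0].min()), int(nz[0].max()) + 1
    x1, x2 = int(nz[1].min()), int(nz[1].max()) + 1
    return BBox(x1, y1, x2, y2)


def resize_with_padding(image: np.ndarray, target: int = 512,
                        order: int = 1) -> tuple[np.ndarray, ResizeTransform]:
    """Scale the longer side to ``target`` and zero-pad right/bottom to square.

    The aspect ratio is preserved; the shorter side is rounded to the
    nearest integer. ``order=1`` (bilinear) suits images and fields,
    ``order=0`` (nearest) suits masks.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel image")
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape
    scale = target / max(h, w)
    new_h = target if h >= w else int(round(h * scale))
    new_w = target if w >= h else int(round(w * scale))
    if (h, w) == (target, target):
        resized = image.astype(np.float32, copy=True)
    else:
        resized = transform.resize(
            image.astype(np.float32), (new_h, new_w), order=order,
            anti_aliasing=False, preserve_range=True, mode="edge",
        ).astype(np.float32)
    out = np.zeros((target, target), dtype=np.float32)
    out[:new_h, :new_w] = resized
    tr = ResizeTransform(
        scale=scale, pad_right=target - new_w, pad_bottom=target - new_h,
        src_shape=(h, w), dst_shape=(target, target),
    )
    return out, tr
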