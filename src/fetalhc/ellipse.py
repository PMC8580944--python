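"""Ellipse fitting on thresholded distance fields and HC measurement.

The network regresses a distance field peaked on the skull contour; pixels
above a superlevel threshold (0.9 by default) are fitted with a
non-iterative, unconstrained least-squares ellipse fit. Head circumference
is the fitted ellipse's perimeter (Ramanujan's second approximation)
converted to millimetres with the per-image pixel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .errors import FitFailureError, NoDetectionError
from .targets import EllipseParams

__all__ = [
    "HCMeasurement",
    "threshold_field",
    "fit_ellipse",
    "ellipse_perimeter_px",
    "hc_mm",
    "measure_ellipse",
]


@dataclass(frozen=True)
class HCMeasurement:
    """A head-circumference measurement for one image."""

    params: EllipseParams
    perimeter_px: float
    mm_per_px: float
    hc_mm: float


def threshold_field(field: np.ndarray, t: float = 0.9,
                    return_weights: bool = False):
    """Coordinates (x, y) of all pixels with ``F >= t``.

    Raises :class:`NoDetectionError` when fewer than 6 pixels survive —
    too few to determine a conic.
    """
    if not (0.0 < t < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    field = np.asarray(field)
    ys, xs = np.nonzero(field >= t)
    if xs.size < 6:
        raise NoDetectionError(
            f"only {xs.size} pixels at or above threshold {t}")
    pts = np.stack([xs, ys], axis=1).astype(np.float64)
    if return_weights:
        return pts, field[ys, xs].astype(np.float64)
    return pts


def _conic_to_params(theta6, mx: float, my: float, sc: float) -> EllipseParams:
    """General conic coefficients (in centered/scaled coords) -> ellipse."""
    A, B, C, D, E, F = theta6
    M = np.array([[A, B / 2.0], [B / 2.0, C]])
    if np.linalg.det(M) <= 1e-12 * max(1.0, A * A + B * B + C * C):
        raise FitFailureError("fitted conic is not an ellipse")
    c = np.linalg.solve(2.0 * M, [-D, -E])
    qc = c @ M @ c + D * c[0] + E * c[1] + F
    lam, vec = np.linalg.eigh(M)  # ascending eigenvalues
    if not (np.all(lam > 0) and qc < 0) and not (np.all(lam < 0) and qc > 0):
        raise FitFailureError("fitted conic is not an ellipse")
    axes2 = -qc / lam
    # smaller eigenvalue -> larger axis -> major direction
    theta = math.atan2(vec[1, 0], vec[0, 0])
    return EllipseParams(
        cx=mx + sc * c[0], cy=my + sc * c[1],
        a=sc * math.sqrt(axes2[0]), b=sc * math.sqrt(axes2[1]), theta=theta,
    ).canonical()


def _signed_distance(pts: np.ndarray, e: EllipseParams,
                     n_samples: int = 2000) -> np.ndarray:
    """Signed Euclidean distance to the ellipse (negative inside)."""
    d, _ = cKDTree(e.sample_points(n_samples)).query(pts, workers=1)
    ct, st = math.cos(e.theta), math.sin(e.theta)
    dx = pts[:, 0] - e.cx
    dy = pts[:, 1] - e.cy
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / e.a) ** 2 + (v / e.b) ** 2 < 1.0
    return np.where(inside, -d, d)


def _boundary_pixels(pts: np.ndarray) -> np.ndarray:
    """Pixels of a rasterized point set adjacent to its complement."""
    pi = np.round(pts).astype(np.int64)
    x1, y1 = pi.min(axis=0)
    x2, y2 = pi.max(axis=0)
    m = np.zeros((y2 - y1 + 3, x2 - x1 + 3), dtype=bool)
    m[pi[:, 1] - y1 + 1, pi[:, 0] - x1 + 1] = True
    inner = ndimage.binary_erosion(m)
    ys, xs = np.nonzero(m & ~inner)
    return np.stack([xs + x1 - 1, ys + y1 - 1], axis=1).astype(np.float64)


def _fit_conic_core(pts: np.ndarray, weights: np.ndarray | None) -> EllipseParams:
    """Unconstrained least-squares conic fit with a fixed number of
    gradient-normalized (geometric-distance) reweightings."""
    mx, my = pts.mean(axis=0)
    sc = pts.std(axis=0).mean()
    if sc <= 0:
        raise FitFailureError("degenerate point set")
    x = (pts[:, 0] - mx) / sc
    y = (pts[:, 1] - my) / sc
    Z = np.stack([x * x, x * y, y * y, x, y, np.ones_like(x)], axis=1)
    w = np.ones(len(x)) if weights is None else np.sqrt(
        np.asarray(weights, dtype=np.float64))
    theta6 = None
    for _ in range(4):
        _, _, vt = np.linalg.svd(Z * w[:, None], full_matrices=False)
        theta6 = vt[-1]
        A, B, C, D, E, _ = theta6
        gx = 2 * A * x + B * y + D
        gy = B * x + 2 * C * y + E
        gn = 1.0 / np.maximum(np.hypot(gx, gy), 1e-9)
        w = gn if weights is None else gn * np.sqrt(
            np.asarray(weights, dtype=np.float64))
    return _conic_to_params(theta6, mx, my, sc)


def fit_ellipse(points: np.ndarray, weights: np.ndarray | None = None,
                refine_band: bool = True) -> EllipseParams:
    """Least-squares ellipse fit for thresholded distance-field pixels.

    Two stages. First, an unconstrained, non-iterative conic fit (smallest
    singular vector of the design matrix, with a fixed number of
    gradient-normalized reweightings that approximate geometric distance);
    this is exact for noise-free samples of an ellipse. Second, when the
    point set forms a thick band — a thresholded distance field keeps every
    pixel within a fixed distance of the contour, and the band's outer ring
    holds more pixels than its inner ring, which biases any plain fit
    outward — the band's boundary pixels are refined against the model of
    two offset curves at signed distance +/-w, recovering the band midline.
    ``refine_band=False`` disables the second stage.

    Raises :class:`FitFailureError` for degenerate input (e.g. collinear
    points) or when the best-fitting conic is not an ellipse.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    if np.unique(pts, axis=0).shape[0] < 6:
        raise FitFailureError("need at least 6 distinct points")

    e0 = _fit_conic_core(pts, weights)
    if not refine_band:
        return e0
    bp = _boundary_pixels(pts)
    s0 = _signed_distance(bp, e0)
    if np.max(np.abs(s0)) < 1.5:  # thin input: nothing to de-bias
        return e0
    sign = np.where(s0 >= 0, 1.0, -1.0)
    x0 = np.array([e0.cx, e0.cy, e0.a, e0.b, e0.theta,
                   float(np.mean(np.abs(s0)))])

    def residuals(x):
        cand = EllipseParams(x[0], x[1], max(abs(x[2]), 1e-3),
                             max(abs(x[3]), 1e-3), x[4])
        return _signed_distance(bp, cand) - sign * x[5]

    try:
        sol = least_squares(residuals, x0, method="lm", xtol=1e-8,
                            ftol=1e-8, max_nfev=200)
        refined = EllipseParams(sol.x[0], sol.x[1], abs(sol.x[2]),
                                abs(sol.x[3]), sol.x[4]).canonical()
    except (ValueError, np.linalg.LinAlgError):
        return e0
    return refined


def ellipse_perimeter_px(params: EllipseParams) -> float:
    """Ramanujan's second perimeter approximation.

    With ``h = ((a-b)/(a+b))^2``:
    ``P = pi (a+b) (1 + 3h / (10 + sqrt(4 - 3h)))``.
    Relative error below 1e-4 for aspect ratios up to 5.
    """
    a, b = params.a, params.b
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def hc_mm(perimeter_px: float, mm_per_px: float) -> float:
    """Head circumference in millimetres: perimeter times pixel size."""
    if perimeter_px <= 0 or mm_per_px <= 0:
        raise ValueError("perimeter and pixel size must be positive")
    return perimeter_px * mm_per_px


def measure_ellipse(params: EllipseParams, mm_per_px: float) -> HCMeasurement:
    """Bundle perimeter and mm conversion for a fitted ellipse."""
    p = ellipse_perimeter_px(params)
    return HCMeasurement(params=params.canonical(), perimeter_px=p,
                         mm_per_px=mm_per_px, hc_mm=hc_mm(p, mm_per_px))
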