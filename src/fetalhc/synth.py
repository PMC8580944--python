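"""Synthetic fetal-ultrasound phantoms.

Each phantom is a grayscale image with one bright elliptical skull band on
a low-frequency soft-tissue background, optional angular shadow sectors,
and multiplicative unit-mean gamma speckle — the structural ingredients of
transthalamic fetal ultrasound that the delineation pipeline must cope
with. Head position, size, axis ratio and orientation are drawn uniformly;
pixel size is drawn with a negative rank correlation to head size through a
Gaussian copula (larger heads are imaged with coarser pixels, as
sonographers zoom out for older fetuses) while keeping an exactly uniform
marginal over the configured range.

This is not a wave-propagation simulator: there is no point-spread
function in polar coordinates, no fan geometry and no anatomy beyond the
skull band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.special import ndtr

from .data import Sample
from .ellipse import ellipse_perimeter_px
from .errors import ConfigError
from .targets import (EllipseParams, FieldConfig, build_distance_field,
                      field_bbox, rasterize_ellipse, skeletonize_contour)

__all__ = [
    "PhantomConfig", "AcousticParams", "ManifestEntry", "DatasetManifest",
    "sample_phantom_params", "render_phantom", "make_sample",
    "synthetic_samples", "build_manifest",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for the generator.

    Defaults target the full 512x512 working resolution; ``desk()`` returns
    the reduced configuration used for CPU-scale experiments (128x128
    images, field thickness r=24). ``size_mm_correlation`` is the magnitude
    of the negative rank correlation between head size and pixel size.
    """

    image_size: int = 512
    a_range: tuple = (70.0, 155.0)
    axis_ratio_range: tuple = (0.6, 0.95)
    skull_thickness_range: tuple = (3.0, 7.0)
    contrast_range: tuple = (0.35, 0.65)
    background_level: float = 0.25
    texture_amp: float = 0.05
    speckle_shape: float = 4.0      # gamma shape; 0 disables speckle
    shadow_probability: float = 0.5
    mm_per_px_range: tuple = (0.052, 0.326)
    size_mm_correlation: float = 0.7
    field_r: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.a_range[0] >= self.a_range[1]:
            raise ConfigError("a_range must be increasing")
        margin = self.skull_thickness_range[1] + self.field_r / 2
        if 2 * (self.a_range[1] + margin) >= self.image_size:
            raise ConfigError("largest head cannot fit inside the image "
                              "with the containment margin")

    @classmethod
    def desk(cls, seed: int = 0) -> "PhantomConfig":
        """Reduced single-CPU configuration: 128px phantoms, r=24."""
        return cls(image_size=128, a_range=(18.0, 38.0),
                   skull_thickness_range=(1.6, 3.5), field_r=24.0, seed=seed)


@dataclass(frozen=True)
class AcousticParams:
    """Per-phantom rendering draw."""

    contrast: float
    skull_thickness: float
    shadow_sectors: tuple      # tuple of (start_rad, width_rad, attenuation)
    texture_seed: int
    speckle_seed: int


@dataclass(frozen=True)
class ManifestEntry:
    name: str
    mm_per_px: float
    params: EllipseParams
    hc_mm: float
    trimester: int


@dataclass
class DatasetManifest:
    entries: list
    config: PhantomConfig

    def __len__(self):
        return len(self.entries)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame([{
            "filename": e.name, "mm_per_px": e.mm_per_px, "hc_mm": e.hc_mm,
            "cx": e.params.cx, "cy": e.params.cy, "a": e.params.a,
            "b": e.params.b, "theta": e.params.theta,
            "trimester": e.trimester,
        } for e in self.entries])


def _ellipse_extents(a: float, b: float, theta: float) -> tuple[float, float]:
    ext_x = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
    ext_y = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
    return ext_x, ext_y


def sample_phantom_params(cfg: PhantomConfig, rng: np.random.Generator):
    """Draw (EllipseParams, AcousticParams, mm_per_px) for one phantom.

    The head is uniformly positioned subject to full containment with a
    margin of skull thickness + r/2; size and pixel size are coupled by a
    Gaussian copula with negative correlation and uniform marginals.
    """
    rho = cfg.size_mm_correlation
    for _ in range(100):
        z1 = rng.standard_normal()
        z2 = -rho * z1 + math.sqrt(1.0 - rho ** 2) * rng.standard_normal()
        u_a, u_mm = ndtr(z1), ndtr(z2)
        a = cfg.a_range[0] + u_a * (cfg.a_range[1] - cfg.a_range[0])
        mm = cfg.mm_per_px_range[0] + u_mm * (
            cfg.mm_per_px_range[1] - cfg.mm_per_px_range[0])
        ratio = rng.uniform(*cfg.axis_ratio_range)
        theta = rng.uniform(0.0, math.pi)
        thick = rng.uniform(*cfg.skull_thickness_range)
        margin = thick + cfg.field_r / 2 + 1
        ext_x, ext_y = _ellipse_extents(a, a * ratio, theta)
        lo_x, hi_x = ext_x + margin, cfg.image_size - ext_x - margin
        lo_y, hi_y = ext_y + margin, cfg.image_size - ext_y - margin
        if lo_x >= hi_x or lo_y >= hi_y:
            continue
        cx = rng.uniform(lo_x, hi_x)
        cy = rng.uniform(lo_y, hi_y)
        sectors = []
        if rng.uniform() < cfg.shadow_probability:
            for _ in range(rng.integers(1, 3)):
                sectors.append((rng.uniform(0, 2 * math.pi),
                                rng.uniform(math.radians(20), math.radians(60)),
                                rng.uniform(0.2, 0.6)))
        acoustic = AcousticParams(
            contrast=rng.uniform(*cfg.contrast_range),
            skull_thickness=thick,
            shadow_sectors=tuple(sectors),
            texture_seed=int(rng.integers(0, 2 ** 31)),
            speckle_seed=int(rng.integers(0, 2 ** 31)),
        )
        params = EllipseParams(cx=cx, cy=cy, a=a, b=a * ratio,
                               theta=theta).canonical()
        return params, acoustic, float(mm)
    raise ConfigError("could not place a head satisfying containment "
                      "after 100 draws; shrink a_range or field_r")


def render_phantom(params: EllipseParams, acoustic: AcousticParams,
                   cfg: PhantomConfig, rng: np.random.Generator | None = None
                   ) -> np.ndarray:
    """Render one 8-bit phantom.

    Background = base level + smoothed zero-mean texture; skull band =
    Gaussian cross-profile (sigma = thickness/2) of the drawn contrast
    around the rasterized contour, attenuated inside shadow sectors;
    speckle = unit-mean gamma noise, spatially smoothed to emulate its
    granular correlation, applied multiplicatively.
    """
    n = cfg.image_size
    t_rng = np.random.default_rng(acoustic.texture_seed)
    bg = np.full((n, n), cfg.background_level, dtype=np.float64)
    if cfg.texture_amp > 0:
        tex = ndimage.gaussian_filter(t_rng.standard_normal((n, n)), n / 16.0)
        sd = tex.std()
        if sd > 0:
            bg += cfg.texture_amp * tex / sd

    contour = rasterize_ellipse(params, n, n, line_width=1.0)
    d = ndimage.distance_transform_edt(contour == 0)
    sigma_t = acoustic.skull_thickness / 2.0
    band = acoustic.contrast * np.exp(-(d ** 2) / (2.0 * sigma_t ** 2))

    if acoustic.shadow_sectors:
        yy, xx = np.mgrid[0:n, 0:n]
        ang = np.arctan2(yy - params.cy, xx - params.cx) % (2 * math.pi)
        for start, width, att in acoustic.shadow_sectors:
            in_sector = ((ang - start) % (2 * math.pi)) < width
            band[in_sector] *= att

    img = bg + band
    if cfg.speckle_shape and cfg.speckle_shape > 0:
        s_rng = np.random.default_rng(acoustic.speckle_seed)
        k = cfg.speckle_shape
        speckle = s_rng.gamma(shape=k, scale=1.0 / k, size=(n, n))
        speckle = ndimage.gaussian_filter(speckle, 0.6)
        img = img * speckle
    return np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)


def make_sample(name: str, params: EllipseParams, acoustic: AcousticParams,
                mm_per_px: float, cfg: PhantomConfig) -> Sample:
    """Render a phantom and derive its regression targets."""
    img = render_phantom(params, acoustic, cfg)
    n = cfg.image_size
    contour = rasterize_ellipse(params, n, n, line_width=2.0)
    skel = skeletonize_contour(contour)
    fld = build_distance_field(skel, FieldConfig(r=cfg.field_r))
    hc = ellipse_perimeter_px(params) * mm_per_px
    return Sample(
        name=name, image=img.astype(np.float32) / 255.0, mm_per_px=mm_per_px,
        field=fld, box=field_bbox(fld), ellipse_net=params,
        ellipse_src=params, transform=None, hc_mm=hc,
    )


def _assign_trimesters(hcs: list) -> list:
    """Tercile labels of HC standing in for gestational trimester."""
    if len(hcs) < 3:
        return [2] * len(hcs)
    q1, q2 = np.quantile(hcs, [1 / 3, 2 / 3])
    return [1 if h <= q1 else (2 if h <= q2 else 3) for h in hcs]


def build_manifest(n: int, cfg: PhantomConfig):
    """Draw ``n`` phantom parameter sets and their manifest."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    draws = [sample_phantom_params(cfg, rng) for _ in range(n)]
    hcs = [ellipse_perimeter_px(p) * mm for p, _, mm in draws]
    trimesters = _assign_trimesters(hcs)
    entries = [ManifestEntry(name=f"{i:03d}_HC.png", mm_per_px=mm, params=p,
                             hc_mm=h, trimester=t)
               for i, ((p, _, mm), h, t) in enumerate(zip(draws, hcs, trimesters))]
    return DatasetManifest(entries=entries, config=cfg), draws


def synthetic_samples(n: int, cfg: PhantomConfig) -> tuple:
    """Generate ``n`` in-memory samples plus their manifest."""
    manifest, draws = build_manifest(n, cfg)
    samples = [make_sample(e.name, p, ac, mm, cfg)
               for e, (p, ac, mm) in zip(manifest.entries, draws)]
    for s, e in zip(samples, manifest.entries):
        s.trimester = e.trimester
    return samples, manifest
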