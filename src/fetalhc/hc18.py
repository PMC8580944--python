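"""Readers and writers for the HC18 dataset layout and related formats.

Layout: ``*.png`` grayscale images, ``*_Annotation.png`` 2-px-wide ellipse
contour rasters, and ``training_set_pixel_size_and_HC.csv`` with columns
``filename``, ``pixel size(mm)``, ``head circumference (mm)``. A COCO-style
annotation JSON (plain JSON: images / annotations / categories, bbox as
[x, y, w, h]) carries the field-derived boxes for training. Distance-field
rasters are stored as 16-bit PNG with value = round(F * 65535). Submission
rows follow the challenge convention: all ellipse quantities in mm, angle
in radians.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .data import Sample
from .ellipse import HCMeasurement, ellipse_perimeter_px, fit_ellipse
from .errors import EmptyAnnotationError, FetalHCError
from .synth import DatasetManifest, PhantomConfig, build_manifest, render_phantom
from .targets import (EllipseParams, FieldConfig, build_distance_field,
                      field_bbox, rasterize_ellipse, resize_with_padding,
                      skeletonize_contour)

__all__ = [
    "generate_dataset", "read_hc18_dataset", "write_submission_csv",
    "write_field_png", "read_field_png", "write_coco_json", "read_coco_json",
    "PIXEL_CSV_NAME",
]

PIXEL_CSV_NAME = "training_set_pixel_size_and_HC.csv"
_CSV_COLUMNS = ["filename", "pixel size(mm)", "head circumference (mm)"]


def write_field_png(field: np.ndarray, path):
    """Store a [0, 1] field as 16-bit PNG (value = round(F * 65535))."""
    arr = np.round(np.clip(field, 0.0, 1.0) * 65535.0).astype(np.uint16)
    iio.imwrite(Path(path), arr)


def read_field_png(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    return arr.astype(np.float32) / 65535.0


def write_coco_json(entries, image_size: int, path):
    """COCO-style annotation JSON with one 'head' record per image."""
    images, annotations = [], []
    for i, (name, bbox) in enumerate(entries):
        images.append({"id": i, "file_name": name,
                       "width": image_size, "height": image_size})
        annotations.append({
            "id": i, "image_id": i, "category_id": 1,
            "bbox": [bbox.x1, bbox.y1, bbox.width, bbox.height],
            "area": bbox.width * bbox.height, "iscrowd": 0,
        })
    doc = {"images": images, "annotations": annotations,
           "categories": [{"id": 1, "name": "head"}]}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco_json(path) -> dict:
    doc = json.loads(Path(path).read_text())
    by_id = {im["id"]: im["file_name"] for im in doc["images"]}
    return {by_id[a["image_id"]]: a["bbox"] for a in doc["annotations"]}


def generate_dataset(n: int, cfg: PhantomConfig, out_dir) -> DatasetManifest:
    """Write an HC18-layout synthetic dataset and its COCO JSON.

    Produces ``*_HC.png`` images, ``*_HC_Annotation.png`` 2-px contour
    rasters, the pixel-size/HC CSV and ``coco_annotations.json`` with the
    field-derived boxes. Deterministic given ``cfg.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest, draws = build_manifest(n, cfg)
    rows, coco = [], []
    for e, (params, acoustic, mm) in zip(manifest.entries, draws):
        img = render_phantom(params, acoustic, cfg)
        iio.imwrite(out / e.name, img)
        contour = rasterize_ellipse(params, cfg.image_size, cfg.image_size,
                                    line_width=2.0)
        iio.imwrite(out / e.name.replace(".png", "_Annotation.png"),
                    (contour * 255).astype(np.uint8))
        fld = build_distance_field(skeletonize_contour(contour),
                                   FieldConfig(r=cfg.field_r))
        coco.append((e.name, field_bbox(fld)))
        rows.append({_CSV_COLUMNS[0]: e.name, _CSV_COLUMNS[1]: mm,
                     _CSV_COLUMNS[2]: e.hc_mm})
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(out / PIXEL_CSV_NAME,
                                                    index=False)
    write_coco_json(coco, cfg.image_size, out / "coco_annotations.json")
    return manifest


def read_hc18_dataset(directory, image_size: int = 512,
                      field_config: FieldConfig = FieldConfig()) -> list:
    """Load an HC18-layout directory into network-resolution samples.

    Per image: pair with its ``_Annotation.png`` and CSV row, recover the
    annotated ellipse (skeletonize + fit, exact for elliptical rasters),
    rescale to the padded square working resolution and rebuild the
    distance-field / box targets there. Files with a missing annotation or
    CSV row are skipped with a warning; an entirely unreadable directory
    raises.
    """
    directory = Path(directory)
    csv_path = directory / PIXEL_CSV_NAME
    if not csv_path.exists():
        raise FileNotFoundError(f"missing {PIXEL_CSV_NAME} in {directory}")
    table = pd.read_csv(csv_path)
    by_name = {row[table.columns[0]]: row for _, row in table.iterrows()}
    samples = []
    image_files = sorted(p for p in directory.glob("*.png")
                         if not p.name.endswith("_Annotation.png"))
    for img_path in image_files:
        ann_path = directory / img_path.name.replace(".png", "_Annotation.png")
        row = by_name.get(img_path.name)
        if row is None or not ann_path.exists():
            warnings.warn(f"skipping {img_path.name}: missing "
                          f"{'CSV row' if row is None else 'annotation'}")
            continue
        try:
            sample = _load_one(img_path, ann_path, row, table.columns,
                               image_size, field_config)
        except FetalHCError as exc:
            warnings.warn(f"skipping {img_path.name}: {exc}")
            continue
        samples.append(sample)
    if not samples:
        raise EmptyAnnotationError(f"no usable samples found in {directory}")
    return samples


def _load_one(img_path, ann_path, row, columns, image_size, field_config):
    img = iio.imread(img_path)
    if img.ndim == 3:
        img = img[..., 0]
    ann = iio.imread(ann_path)
    if ann.ndim == 3:
        ann = ann[..., 0]
    mm_per_px = float(row[columns[1]])
    hc = float(row[columns[2]]) if len(columns) > 2 and not pd.isna(
        row[columns[2]]) else None

    skel_src = skeletonize_contour(ann > 0)
    ys, xs = np.nonzero(skel_src)
    ell_src = fit_ellipse(np.stack([xs, ys], axis=1).astype(np.float64))
    net_img, tr = resize_with_padding(img.astype(np.float32) / 255.0,
                                      image_size)
    s = tr.scale
    ell_net = EllipseParams(cx=ell_src.cx * s, cy=ell_src.cy * s,
                            a=ell_src.a * s, b=ell_src.b * s,
                            theta=ell_src.theta).canonical()
    contour_net = rasterize_ellipse(ell_net, image_size, image_size,
                                    line_width=2.0)
    fld = build_distance_field(skeletonize_contour(contour_net), field_config)
    if hc is None:
        hc = ellipse_perimeter_px(ell_src) * mm_per_px
    return Sample(
        name=img_path.name, image=net_img, mm_per_px=mm_per_px, field=fld,
        box=field_bbox(fld), ellipse_net=ell_net, ellipse_src=ell_src,
        transform=tr, hc_mm=hc,
    )


def write_submission_csv(measurements, path):
    """Challenge-style submission rows, one per image.

    ``measurements`` maps filename -> :class:`HCMeasurement` or None
    (a dict or an iterable of pairs); pixel quantities are converted to
    mm, the angle stays in radians in [0, pi). No-measurement rows keep
    the filename with empty cells. Duplicate filenames raise.
    """
    pairs = list(measurements.items()) if isinstance(measurements, dict) \
        else list(measurements)
    names = [n for n, _ in pairs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate filenames in submission")
    rows = []
    for name, m in pairs:
        if m is None:
            rows.append({"filename": name})
            continue
        p = m.params.canonical()
        rows.append({
            "filename": name,
            "center_x_mm": p.cx * m.mm_per_px,
            "center_y_mm": p.cy * m.mm_per_px,
            "semi_axes_a_mm": p.a * m.mm_per_px,
            "semi_axes_b_mm": p.b * m.mm_per_px,
            "angle_rad": p.theta,
        })
    cols = ["filename", "center_x_mm", "center_y_mm", "semi_axes_a_mm",
            "semi_axes_b_mm", "angle_rad"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
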