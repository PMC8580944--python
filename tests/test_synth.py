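"""Phantom generator statistics and HC18-layout IO round trips."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from fetalhc.ellipse import ellipse_perimeter_px
from fetalhc.errors import ConfigError
from fetalhc.hc18 import (PIXEL_CSV_NAME, generate_dataset, read_coco_json,
                          read_field_png, read_hc18_dataset,
                          write_field_png, write_submission_csv)
from fetalhc.synth import (PhantomConfig, render_phantom,
                           sample_phantom_params, synthetic_samples)
from fetalhc.targets import EllipseParams
from fetalhc.ellipse import HCMeasurement, measure_ellipse


class TestSampling:
    def test_fixed_seed_identical_draw(self, phantom_cfg):
        d1 = sample_phantom_params(phantom_cfg, np.random.default_rng(7))
        d2 = sample_phantom_params(phantom_cfg, np.random.default_rng(7))
        assert d1[0] == d2[0] and d1[2] == d2[2]

    def test_containment_margin(self, phantom_cfg):
        rng = np.random.default_rng(1)
        n = phantom_cfg.image_size
        for _ in range(100):
            p, ac, _ = sample_phantom_params(phantom_cfg, rng)
            margin = ac.skull_thickness + phantom_cfg.field_r / 2
            ext_x = math.sqrt((p.a * math.cos(p.theta)) ** 2
                              + (p.b * math.sin(p.theta)) ** 2)
            ext_y = math.sqrt((p.a * math.sin(p.theta)) ** 2
                              + (p.b * math.cos(p.theta)) ** 2)
            assert p.cx - ext_x >= margin and p.cx + ext_x <= n - margin
            assert p.cy - ext_y >= margin and p.cy + ext_y <= n - margin

    def test_mm_per_px_within_configured_range(self, phantom_cfg):
        rng = np.random.default_rng(2)
        lo, hi = phantom_cfg.mm_per_px_range
        mms = [sample_phantom_params(phantom_cfg, rng)[2] for _ in range(200)]
        assert min(mms) >= lo and max(mms) <= hi

    def test_marginals_match_configured_distributions(self, phantom_cfg):
        """KS tests at alpha=0.01 for a, axis ratio, theta, mm_per_px."""
        rng = np.random.default_rng(3)
        draws = [sample_phantom_params(phantom_cfg, rng) for _ in range(200)]
        a = np.array([d[0].a for d in draws])
        ratio = np.array([d[0].b / d[0].a for d in draws])
        theta = np.array([d[0].theta for d in draws])
        mm = np.array([d[2] for d in draws])
        for vals, (lo, hi) in [
                (a, phantom_cfg.a_range),
                (ratio, phantom_cfg.axis_ratio_range),
                (theta, (0.0, math.pi)),
                (mm, phantom_cfg.mm_per_px_range)]:
            p = stats.kstest(vals, stats.uniform(lo, hi - lo).cdf).pvalue
            assert p > 0.01

    def test_size_pixelsize_negatively_correlated(self, phantom_cfg):
        rng = np.random.default_rng(4)
        draws = [sample_phantom_params(phantom_cfg, rng) for _ in range(200)]
        a = [d[0].a for d in draws]
        mm = [d[2] for d in draws]
        assert np.corrcoef(a, mm)[0, 1] < -0.4

    def test_infeasible_containment_raises(self):
        with pytest.raises(ConfigError):
            PhantomConfig(image_size=128, a_range=(50.0, 60.0), field_r=100.0)


class TestRendering:
    def test_contour_brightness_matches_drawn_contrast(self):
        cfg = PhantomConfig.desk(seed=0)
        cfg = PhantomConfig(**{**cfg.__dict__, "texture_amp": 0.0,
                               "speckle_shape": 0.0,
                               "shadow_probability": 0.0})
        rng = np.random.default_rng(5)
        p, ac, _ = sample_phantom_params(cfg, rng)
        img = render_phantom(p, ac, cfg).astype(np.float64) / 255.0
        from fetalhc.targets import rasterize_ellipse
        contour = rasterize_ellipse(p, cfg.image_size, cfg.image_size, 1.0)
        on = img[contour > 0].mean()
        far = img[:20, :20].mean()  # corner, far from the head
        assert on - far == pytest.approx(ac.contrast, rel=0.02)

    def test_unit_mean_speckle_preserves_image_mean(self):
        cfg = PhantomConfig(seed=0)  # 512px for a tight law-of-large-numbers
        rng = np.random.default_rng(6)
        p, ac, _ = sample_phantom_params(cfg, rng)
        with_speckle = render_phantom(p, ac, cfg).mean()
        quiet_cfg = PhantomConfig(**{**cfg.__dict__, "speckle_shape": 0.0})
        without = render_phantom(p, ac, quiet_cfg).mean()
        assert with_speckle == pytest.approx(without, rel=0.02)

    def test_same_seed_bit_identical(self, phantom_cfg):
        rng = np.random.default_rng(8)
        p, ac, _ = sample_phantom_params(phantom_cfg, rng)
        i1 = render_phantom(p, ac, phantom_cfg)
        i2 = render_phantom(p, ac, phantom_cfg)
        assert np.array_equal(i1, i2)

    def test_sample_passes_target_invariants(self, small_samples):
        for s in small_samples:
            assert s.field.min() >= 0.0 and s.field.max() == 1.0
            assert s.image.min() >= 0.0 and s.image.max() <= 1.0
            assert s.hc_mm == pytest.approx(
                ellipse_perimeter_px(s.ellipse_net) * s.mm_per_px, rel=1e-9)


class TestDatasetIO:
    @pytest.fixture(scope="class")
    def dataset_dir(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("hc18")
        cfg = PhantomConfig(image_size=256, a_range=(40.0, 80.0),
                            skull_thickness_range=(2.0, 5.0), field_r=48.0,
                            seed=21)
        manifest = generate_dataset(6, cfg, out)
        return out, cfg, manifest

    def test_file_counts(self, dataset_dir):
        out, _, manifest = dataset_dir
        imgs = [p for p in out.glob("*.png")
                if not p.name.endswith("_Annotation.png")]
        anns = list(out.glob("*_Annotation.png"))
        assert len(imgs) == len(anns) == len(manifest) == 6
        import pandas as pd
        csv = pd.read_csv(out / PIXEL_CSV_NAME)
        assert len(csv) == 6
        assert len(read_coco_json(out / "coco_annotations.json")) == 6

    def test_csv_hc_is_perimeter_times_pixel_size(self, dataset_dir):
        out, _, manifest = dataset_dir
        import pandas as pd
        csv = pd.read_csv(out / PIXEL_CSV_NAME).set_index("filename")
        for e in manifest.entries:
            expected = ellipse_perimeter_px(e.params) * e.mm_per_px
            assert csv.loc[e.name][1] == pytest.approx(expected, abs=1e-6)

    def test_read_back_round_trip(self, dataset_dir):
        out, cfg, manifest = dataset_dir
        from fetalhc.targets import FieldConfig
        samples = read_hc18_dataset(out, image_size=cfg.image_size,
                                    field_config=FieldConfig(r=cfg.field_r))
        assert len(samples) == 6
        by_name = {e.name: e for e in manifest.entries}
        for s in samples:
            e = by_name[s.name]
            assert s.mm_per_px == pytest.approx(e.mm_per_px, abs=1e-9)
            assert math.hypot(s.ellipse_src.cx - e.params.cx,
                              s.ellipse_src.cy - e.params.cy) < 2.0
            assert abs(s.ellipse_src.a - e.params.a) < 2.0
            assert abs(s.ellipse_src.b - e.params.b) < 2.0
            dth = abs((s.ellipse_src.theta - e.params.theta + math.pi / 2)
                      % math.pi - math.pi / 2)
            assert math.degrees(dth) < 2.0 or e.params.b / e.params.a > 0.9
            assert s.field.max() == 1.0

    def test_byte_reproducible(self, tmp_path):
        cfg = PhantomConfig.desk(seed=33)
        generate_dataset(3, cfg, tmp_path / "a")
        generate_dataset(3, cfg, tmp_path / "b")
        for pa in sorted((tmp_path / "a").iterdir()):
            pb = tmp_path / "b" / pa.name
            assert pa.read_bytes() == pb.read_bytes()

    def test_orphan_image_skipped_with_warning(self, dataset_dir, tmp_path):
        out, cfg, _ = dataset_dir
        import shutil
        d = tmp_path / "orphan"
        d.mkdir()
        shutil.copy(out / PIXEL_CSV_NAME, d / PIXEL_CSV_NAME)
        src = next(p for p in out.glob("*.png")
                   if not p.name.endswith("_Annotation.png"))
        shutil.copy(src, d / src.name)  # image without annotation
        other = [p for p in out.glob("*.png")
                 if not p.name.endswith("_Annotation.png")][1]
        shutil.copy(other, d / other.name)
        shutil.copy(out / other.name.replace(".png", "_Annotation.png"),
                    d / other.name.replace(".png", "_Annotation.png"))
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            samples = read_hc18_dataset(d, image_size=cfg.image_size)
        assert len(samples) == 1
        assert any("skipping" in str(x.message) for x in w)

    def test_field_png_round_trip(self, tmp_path, rng):
        f = rng.uniform(size=(32, 32)).astype(np.float32)
        write_field_png(f, tmp_path / "f.png")
        back = read_field_png(tmp_path / "f.png")
        assert np.abs(back - f).max() <= 0.5 / 65535 + 1e-7


class TestSubmission:
    def test_row_format(self, tmp_path):
        m = measure_ellipse(EllipseParams(100, 120, 80, 60, 0.3), 0.1)
        path = tmp_path / "sub.csv"
        write_submission_csv({"img.png": m}, path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df.columns) == ["filename", "center_x_mm", "center_y_mm",
                                    "semi_axes_a_mm", "semi_axes_b_mm",
                                    "angle_rad"]
        assert len(df) == 1
        assert df.semi_axes_a_mm[0] >= df.semi_axes_b_mm[0]
        assert 0 <= df.angle_rad[0] < math.pi
        assert df.center_x_mm[0] == pytest.approx(100 * 0.1)

    def test_missing_measurement_flagged(self, tmp_path):
        m = measure_ellipse(EllipseParams(10, 10, 8, 6), 0.2)
        path = tmp_path / "sub.csv"
        write_submission_csv({"a.png": m, "b.png": None}, path)
        import pandas as pd
        df = pd.read_csv(path)
        assert len(df) == 2
        assert df[df.filename == "b.png"].center_x_mm.isna().all()

    def test_duplicate_filenames_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_submission_csv([("x.png", None), ("x.png", None)],
                                 tmp_path / "s.csv")
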