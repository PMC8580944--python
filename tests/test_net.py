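"""Architecture contracts: anchors, proposals, pyramid, heads."""

import math
import time

import numpy as np
import pytest

from fetalhc import boxes as B
from fetalhc.errors import ConfigError
from fetalhc.net import (FPN_STRIDES, MaskR2CNN, NetConfig, assign_fpn_levels,
                         generate_anchors, propose_rois)
from fetalhc.nn.tensor import Tensor, no_grad

from conftest import desk_net_config


def pyramid_shapes(size):
    return [(size // s, size // s) for s in FPN_STRIDES]


class TestAnchors:
    def test_total_count_512(self, desk_cfg):
        cfg = NetConfig()  # full-scale defaults
        a = generate_anchors(cfg, pyramid_shapes(512))
        assert a.shape[0] == 3 * (128 ** 2 + 64 ** 2 + 32 ** 2 + 16 ** 2 + 8 ** 2)
        assert a.shape[0] == 65472

    def test_count_formula_other_sizes(self, desk_cfg):
        for size in (128, 192, 256):
            a = generate_anchors(desk_cfg, pyramid_shapes(size))
            expected = 3 * sum((size // s) ** 2 for s in FPN_STRIDES)
            assert a.shape[0] == expected

    def test_ratio_one_anchors_square(self, desk_cfg):
        a = generate_anchors(desk_cfg, pyramid_shapes(128))
        w = a[:, 2] - a[:, 0]
        h = a[:, 3] - a[:, 1]
        square = np.isclose(w, h)
        assert square.sum() == a.shape[0] // 3

    def test_scale_ratio_geometry(self):
        cfg = NetConfig()
        a = generate_anchors(cfg, pyramid_shapes(512))
        # level 2 (scale 64), first cell, ratio 0.5 anchor
        lvl2 = a[3 * 128 ** 2:]
        w = lvl2[0, 2] - lvl2[0, 0]
        h = lvl2[0, 3] - lvl2[0, 1]
        assert w == pytest.approx(64 * math.sqrt(0.5), rel=1e-6)
        assert h == pytest.approx(64 / math.sqrt(0.5), rel=1e-6)


class TestBoxCodec:
    def test_encode_decode_inverse(self, rng):
        anchors = rng.uniform(10, 200, (50, 4))
        anchors[:, 2:] = anchors[:, :2] + rng.uniform(5, 80, (50, 2))
        boxes = rng.uniform(10, 200, (50, 4))
        boxes[:, 2:] = boxes[:, :2] + rng.uniform(5, 80, (50, 2))
        d = B.encode_deltas(boxes, anchors)
        back = B.decode_deltas(d, anchors)
        assert np.abs(back - boxes).max() < 1e-6

    def test_zero_deltas_identity(self, rng):
        anchors = np.array([[10.0, 10.0, 42.0, 42.0]])
        out = B.decode_deltas(np.zeros((1, 4)), anchors)
        assert np.allclose(out, anchors)

    def test_log2_delta_doubles_box(self):
        anchor = np.array([[0.0, 0.0, 32.0, 32.0]])
        d = np.array([[0.0, 0.0, math.log(2), math.log(2)]])
        out = B.decode_deltas(d, anchor)[0]
        assert (out[2] - out[0], out[3] - out[1]) == (64.0, 64.0)
        assert (out[0] + out[2]) / 2 == 16.0  # same center


class TestProposals:
    def test_zero_deltas_returns_clipped_anchors(self, desk_cfg):
        anchors = generate_anchors(desk_cfg, pyramid_shapes(128))
        scores = np.linspace(1, 0, anchors.shape[0])
        props, _ = propose_rois(anchors, scores, np.zeros_like(anchors),
                                0.7, 100, 10, 128)
        clipped = B.clip_boxes(anchors[:100], 128)
        # every proposal is one of the clipped top-100 anchors
        assert all(any(np.allclose(p, c) for c in clipped) for p in props)

    def test_duplicate_boxes_suppressed(self):
        anchors = np.array([[10.0, 10.0, 50.0, 50.0]] * 2)
        props, _ = propose_rois(anchors, np.array([0.9, 0.8]),
                                np.zeros((2, 4)), 0.7, 10, 10, 128)
        assert props.shape[0] == 1

    def test_nms_keeps_best_scoring(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [30, 30, 40, 40.0]])
        keep = B.nms(boxes, np.array([0.5, 0.9, 0.7]), 0.5)
        assert list(keep) == [1, 2]

    def test_fpn_level_heuristic(self):
        rois = np.array([[0, 0, 224, 224], [0, 0, 56, 56], [0, 0, 900, 900.0]])
        assert list(assign_fpn_levels(rois)) == [4, 2, 5]


class TestPyramidAndHeads:
    def test_pyramid_strides_128(self, desk_cfg):
        model = MaskR2CNN(desk_cfg, seed=0)
        with no_grad():
            pyr = model.build_feature_pyramid(
                model.prepare_image(np.zeros((128, 128), np.float32)))
        assert [p.data.shape[2] for p in pyr] == [32, 16, 8, 4, 2]
        assert all(p.data.shape[1] == desk_cfg.fpn_channels for p in pyr)

    def test_pyramid_strides_512(self):
        cfg = desk_net_config(image_size=512,
                              anchor_scales=(32, 64, 128, 256, 512))
        model = MaskR2CNN(cfg, seed=0)
        with no_grad():
            pyr = model.build_feature_pyramid(
                model.prepare_image(np.zeros((512, 512), np.float32)))
        assert [p.data.shape[2] for p in pyr] == [128, 64, 32, 16, 8]

    def test_default_config_follows_reference_values(self):
        cfg = NetConfig()
        assert cfg.fpn_channels == 256 and cfg.roi_size == 14
        assert cfg.anchor_scales == (32, 64, 128, 256, 512)
        assert cfg.anchor_ratios == (0.5, 1.0, 2.0)
        assert cfg.train_rois_per_image == 150
        assert cfg.backbone_depth == 101

    def test_input_not_divisible_by_64_raises(self, desk_cfg):
        model = MaskR2CNN(desk_cfg, seed=0)
        with pytest.raises(ConfigError):
            model.prepare_image(np.zeros((100, 100), np.float32))

    def test_rpn_output_aligned_with_anchors(self, desk_cfg):
        model = MaskR2CNN(desk_cfg, seed=0)
        with no_grad():
            pyr = model.build_feature_pyramid(
                model.prepare_image(np.zeros((128, 128), np.float32)))
            logits, deltas = model.rpn(pyr)
        n = model.anchors_for(128).shape[0]
        assert logits.data.shape == (n,)
        assert deltas.data.shape == (n, 4)
        obj = 1 / (1 + np.exp(-logits.data))
        assert obj.min() >= 0 and obj.max() <= 1

    def test_rpn_deterministic(self, desk_cfg, rng):
        img = rng.uniform(size=(128, 128)).astype(np.float32)
        outs = []
        for _ in range(2):
            model = MaskR2CNN(desk_cfg, seed=7)
            model.eval()
            with no_grad():
                pyr = model.build_feature_pyramid(model.prepare_image(img))
                logits, _ = model.rpn(pyr)
            outs.append(logits.data.copy())
        assert np.array_equal(outs[0], outs[1])

    def test_class_head_softmax_and_shapes(self, desk_cfg, rng):
        model = MaskR2CNN(desk_cfg, seed=0)
        patches = Tensor(rng.standard_normal(
            (5, desk_cfg.fpn_channels, 7, 7)).astype(np.float32))
        with no_grad():
            cls_logits, box = model.classbox(patches)
        assert cls_logits.data.shape == (5, 2)
        assert box.data.shape == (5, 4)
        z = np.exp(cls_logits.data - cls_logits.data.max(1, keepdims=True))
        assert np.allclose((z / z.sum(1, keepdims=True)).sum(1), 1.0)

    def test_no_class_head_variant(self):
        cfg = desk_net_config(include_class_head=False)
        model = MaskR2CNN(cfg, seed=0)
        assert model.classbox is None
        dets = model.full_forward(np.zeros((128, 128), np.float32))
        assert isinstance(dets, list)

    @pytest.mark.parametrize("d", [10, 14])
    @pytest.mark.parametrize("u", [1, 2, 3])
    @pytest.mark.parametrize("variant", ["upconv", "transposed"])
    def test_field_head_output_size(self, d, u, variant):
        cfg = desk_net_config(roi_size=d, n_upsamplings=u,
                              upsampling_variant=variant,
                              fpn_channels=8, head_channels=8)
        model = MaskR2CNN(cfg, seed=0)
        with no_grad():
            out = model.fieldhead(Tensor(np.zeros((2, 8, d, d), np.float32)))
        assert out.data.shape == (2, 1, (2 ** u) * d, (2 ** u) * d)

    def test_unsupported_upsampling_count(self):
        with pytest.raises(ConfigError):
            desk_net_config(n_upsamplings=4)

    def test_roi_align_multilevel_order_and_shape(self, desk_cfg, rng):
        model = MaskR2CNN(desk_cfg, seed=0)
        with no_grad():
            pyr = model.build_feature_pyramid(
                model.prepare_image(rng.uniform(size=(128, 128)).astype(np.float32)))
            rois = np.array([[4.0, 4.0, 60.0, 60.0],    # P2-sized
                             [0.0, 0.0, 128.0, 128.0],  # larger -> higher level
                             [10.0, 10.0, 70.0, 66.0]])
            patches = model.roi_align_patches(pyr, rois)
            assert patches.data.shape == (3, desk_cfg.fpn_channels, 7, 7)
            # order preserved: recompute ROI 1 alone and compare
            alone = model.roi_align_patches(pyr, rois[1:2])
        assert np.allclose(patches.data[1], alone.data[0], atol=1e-6)

    def test_zero_area_roi_raises(self, desk_cfg):
        model = MaskR2CNN(desk_cfg, seed=0)
        with no_grad():
            pyr = model.build_feature_pyramid(
                model.prepare_image(np.zeros((128, 128), np.float32)))
            with pytest.raises(ValueError):
                model.roi_align_patches(pyr, np.array([[5.0, 5.0, 5.0, 9.0]]))


class TestFullForward:
    def test_detection_invariants_random_weights(self, desk_cfg, rng):
        model = MaskR2CNN(desk_cfg, seed=3)
        dets = model.full_forward(rng.uniform(size=(128, 128)).astype(np.float32))
        S = desk_cfg.field_patch_size
        for d in dets:
            assert 0.0 <= d.score <= 1.0
            assert d.cls == "head"
            assert d.field_patch.shape == (S, S)
            assert d.field_patch.min() >= 0.0 and d.field_patch.max() <= 1.0
            assert d.box.x2 > d.box.x1 and d.box.y2 > d.box.y1

    def test_cpu_forward_under_two_seconds(self, desk_cfg):
        model = MaskR2CNN(desk_cfg, seed=0)
        img = np.zeros((128, 128), np.float32)
        model.full_forward(img)  # warm
        t0 = time.time()
        model.full_forward(img)
        assert time.time() - t0 < 2.0
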