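"""The detector-regressor: ResNet/FPN backbone, RPN, ROI align, three heads.

The architecture follows Mask-RCNN, with the segmentation head replaced by
a distance-field regression head whose upsampling path is either a stack of
transposed convolutions or UNet-style up-convolutions (2x nearest upsample
followed by a 2x2 convolution and two 3x3 convolutions), selected by
``NetConfig.upsampling_variant`` / ``n_upsamplings``. The classification
head can be disabled entirely, in which case detections are scored by RPN
objectness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import boxes as B
from . import nn
from .errors import ConfigError
from .nn import ops
from .nn.tensor import Tensor, no_grad
from .targets import BBox

__all__ = [
    "NetConfig", "Detection", "MaskR2CNN", "generate_anchors", "propose_rois",
    "FPN_STRIDES",
]

FPN_STRIDES = (4, 8, 16, 32, 64)

_RESNET_SPECS = {
    18: ("basic", (2, 2, 2, 2)),
    34: ("basic", (3, 4, 6, 3)),
    50: ("bottleneck", (3, 4, 6, 3)),
    101: ("bottleneck", (3, 4, 23, 3)),
}


@dataclass(frozen=True)
class NetConfig:
    """Architecture and detection hyper-parameters.

    Defaults follow the full-scale configuration (ResNet-101 FPN, 512x512
    input, ROI align output 14x14, 150 training ROIs). ``width_mult``
    scales every channel count; ``head_channels`` / ``fc_channels`` size
    the field-regression and dense heads. Detection hyper-parameters not
    restated by the reference configuration take the standard Mask-RCNN
    values.
    """

    image_size: int = 512
    in_channels: int = 1
    backbone_depth: int = 101
    width_mult: float = 1.0
    fpn_channels: int = 256
    roi_size: int = 14
    anchor_scales: tuple = (32, 64, 128, 256, 512)
    anchor_ratios: tuple = (0.5, 1.0, 2.0)
    upsampling_variant: str = "upconv"
    n_upsamplings: int = 3
    include_class_head: bool = True
    head_channels: int = 256
    fc_channels: int = 1024
    train_rois_per_image: int = 150
    max_positive_rois: int | None = None  # default: train_rois_per_image // 4
    # standard Mask-RCNN values for the hyper-parameters the reference
    # configuration inherits without restating
    rpn_pos_iou: float = 0.7
    rpn_neg_iou: float = 0.3
    rpn_nms_thresh: float = 0.7
    rpn_train_anchors: int = 256
    head_pos_iou: float = 0.5
    score_thresh: float = 0.7
    det_nms_thresh: float = 0.3
    pre_nms_train: int = 6000
    post_nms_train: int = 1000
    pre_nms_test: int = 1000
    post_nms_test: int = 100

    def __post_init__(self):
        if self.backbone_depth not in _RESNET_SPECS:
            raise ConfigError(f"unsupported backbone depth {self.backbone_depth}")
        if len(self.anchor_scales) != len(FPN_STRIDES):
            raise ConfigError("one anchor scale per pyramid level is required")
        if self.roi_size < 2:
            raise ConfigError("roi_size must be >= 2")
        if self.n_upsamplings < 1 or self.n_upsamplings > 3:
            raise ConfigError("n_upsamplings must be in {1, 2, 3}")
        if self.upsampling_variant not in ("upconv", "transposed"):
            raise ConfigError("upsampling_variant must be 'upconv' or 'transposed'")
        if self.image_size % 64:
            raise ConfigError("image size must be divisible by 64")

    @property
    def field_patch_size(self) -> int:
        return self.roi_size * (2 ** self.n_upsamplings)


@dataclass
class Detection:
    """One scored head detection with its regressed field patch."""

    box: BBox
    score: float
    cls: str
    field_patch: np.ndarray  # (S, S), clipped to [0, 1]


# ---------------------------------------------------------------------------
# anchors / proposals


def generate_anchors(cfg: NetConfig, pyramid_shapes) -> np.ndarray:
    """All anchors in input coordinates, ordered level -> row -> col -> ratio.

    Per cell, anchor width/height are ``s*sqrt(ratio)`` / ``s/sqrt(ratio)``
    with ratio = width/height, centered on the cell center.
    """
    out = []
    for (h, w), stride, scale in zip(pyramid_shapes, FPN_STRIDES, cfg.anchor_scales):
        cy = (np.arange(h) + 0.5) * stride
        cx = (np.arange(w) + 0.5) * stride
        ws = np.array([scale * math.sqrt(r) for r in cfg.anchor_ratios])
        hs = np.array([scale / math.sqrt(r) for r in cfg.anchor_ratios])
        gy, gx, ai = np.meshgrid(cy, cx, np.arange(len(cfg.anchor_ratios)),
                                 indexing="ij")
        aw = ws[ai]
        ah = hs[ai]
        out.append(np.stack([gx - aw / 2, gy - ah / 2, gx + aw / 2, gy + ah / 2],
                            axis=-1).reshape(-1, 4))
    return np.concatenate(out, axis=0).astype(np.float64)


def propose_rois(anchors: np.ndarray, objectness: np.ndarray,
                 deltas: np.ndarray, nms_thresh: float, pre_nms_k: int,
                 post_nms_k: int, image_size: int):
    """Decode, clip, NMS-filter RPN outputs into proposals.

    Returns (boxes (n, 4), scores (n,)).
    """
    order = np.argsort(-objectness, kind="stable")[:pre_nms_k]
    boxes = B.decode_deltas(deltas[order], anchors[order])
    boxes = B.clip_boxes(boxes, image_size)
    scores = objectness[order]
    wh = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    valid = wh > 1.0
    boxes, scores = boxes[valid], scores[valid]
    if boxes.shape[0] == 0:
        return boxes, scores
    keep = B.nms(boxes, scores, nms_thresh, max_keep=post_nms_k)
    return boxes[keep], scores[keep]


def assign_fpn_levels(rois: np.ndarray, k0: int = 4, canonical: float = 224.0):
    """Standard FPN level heuristic: k = floor(k0 + log2(sqrt(wh)/224))."""
    w = np.maximum(rois[:, 2] - rois[:, 0], 1e-6)
    h = np.maximum(rois[:, 3] - rois[:, 1], 1e-6)
    k = np.floor(k0 + np.log2(np.sqrt(w * h) / canonical))
    return np.clip(k, 2, 5).astype(np.int64)


# ---------------------------------------------------------------------------
# backbone


class _BasicBlock(nn.Module):
    expansion = 1

    def __init__(self, cin, cout, stride, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng, stride=stride, bias=False)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, bias=False)
        self.bn2 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down_conv = nn.Conv2d(cin, cout, 1, rng, stride=stride, bias=False)
            self.down_bn = nn.BatchNorm2d(cout)
        else:
            self.down_conv = None

    def forward(self, x):
        y = ops.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        sc = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return ops.relu(ops.add(y, sc))


class _Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, cin, cmid, stride, rng):
        super().__init__()
        cout = cmid * 4
        self.conv1 = nn.Conv2d(cin, cmid, 1, rng, bias=False)
        self.bn1 = nn.BatchNorm2d(cmid)
        self.conv2 = nn.Conv2d(cmid, cmid, 3, rng, stride=stride, bias=False)
        self.bn2 = nn.BatchNorm2d(cmid)
        self.conv3 = nn.Conv2d(cmid, cout, 1, rng, bias=False)
        self.bn3 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down_conv = nn.Conv2d(cin, cout, 1, rng, stride=stride, bias=False)
            self.down_bn = nn.BatchNorm2d(cout)
        else:
            self.down_conv = None

    def forward(self, x):
        y = ops.relu(self.bn1(self.conv1(x)))
        y = ops.relu(self.bn2(self.conv2(y)))
        y = self.bn3(self.conv3(y))
        sc = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return ops.relu(ops.add(y, sc))


class ResNetBody(nn.Module):
    """Residual body producing C2..C5 at strides 4, 8, 16, 32."""

    def __init__(self, cfg: NetConfig, rng):
        super().__init__()
        kind, counts = _RESNET_SPECS[cfg.backbone_depth]
        w = cfg.width_mult
        base = [max(4, int(round(64 * w))), max(4, int(round(128 * w))),
                max(4, int(round(256 * w))), max(8, int(round(512 * w)))]
        stem_c = base[0]
        self.stem_conv = nn.Conv2d(cfg.in_channels, stem_c, 7, rng, stride=2, bias=False)
        self.stem_bn = nn.BatchNorm2d(stem_c)
        block = _BasicBlock if kind == "basic" else _Bottleneck
        self.out_channels = []
        cin = stem_c
        self.stages = []
        for si, (cmid, n) in enumerate(zip(base, counts)):
            blocks = []
            for bi in range(n):
                stride = 2 if (si > 0 and bi == 0) else 1
                blocks.append(block(cin, cmid, stride, rng))
                cin = cmid * block.expansion
            self.stages.append(nn.Sequential(*blocks))
            self.out_channels.append(cin)

    def forward(self, x):
        x = ops.relu(self.stem_bn(self.stem_conv(x)))
        x = ops.maxpool2d(x, k=3, stride=2, pad=1)
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats  # C2, C3, C4, C5


class FPN(nn.Module):
    """Top-down pathway with 1x1 lateral connections; P6 by stride-2
    subsampling of P5."""

    def __init__(self, in_channels, out_channels, rng):
        super().__init__()
        self.laterals = [nn.Conv2d(c, out_channels, 1, rng) for c in in_channels]
        self.smooth = [nn.Conv2d(out_channels, out_channels, 3, rng)
                       for _ in in_channels]

    def forward(self, feats):
        c2, c3, c4, c5 = feats
        p5 = self.laterals[3](c5)
        p4 = ops.add(self.laterals[2](c4), ops.upsample2x(p5))
        p3 = ops.add(self.laterals[1](c3), ops.upsample2x(p4))
        p2 = ops.add(self.laterals[0](c2), ops.upsample2x(p3))
        p2, p3, p4, p5 = (s(p) for s, p in
                          zip(self.smooth, (p2, p3, p4, p5)))
        p6 = ops.subsample2(p5)
        return [p2, p3, p4, p5, p6]


class RPNHead(nn.Module):
    """Shared-weight objectness + box-delta head over all pyramid levels."""

    def __init__(self, channels, n_anchors, rng):
        super().__init__()
        self.conv = nn.Conv2d(channels, channels, 3, rng)
        self.cls = nn.Conv2d(channels, n_anchors, 1, rng, init_scale=0.1)
        self.reg = nn.Conv2d(channels, n_anchors * 4, 1, rng, init_scale=0.1)

    def forward(self, pyramid):
        logits, deltas = [], []
        for p in pyramid:
            t = ops.relu(self.conv(p))
            cl = self.cls(t)  # (1, A, H, W)
            rg = self.reg(t)  # (1, 4A, H, W)
            n, a, h, w = cl.data.shape
            logits.append(_reshape_rpn(cl, (0, 2, 3, 1), (-1,)))
            deltas.append(_reshape_rpn(rg, (0, 2, 3, 1), (-1, 4)))
        return ops.concat_rows(logits), ops.concat_rows(deltas)


def _reshape_rpn(x: Tensor, perm, shape) -> Tensor:
    orig = x.data.shape
    out = np.ascontiguousarray(x.data.transpose(perm)).reshape(shape)

    def grad(g):
        inv = np.argsort(perm)
        return g.reshape([orig[i] for i in perm]).transpose(inv)

    from .nn.tensor import make
    return make(out, [(x, grad)])


class ClassBoxHead(nn.Module):
    """Two shared 1024-wide dense layers, then 2-way softmax scores and
    4 linearly-activated box-refinement factors for the head class."""

    def __init__(self, cfg: NetConfig, rng):
        super().__init__()
        din = cfg.fpn_channels * cfg.roi_size * cfg.roi_size
        self.fc1 = nn.Linear(din, cfg.fc_channels, rng)
        self.fc2 = nn.Linear(cfg.fc_channels, cfg.fc_channels, rng)
        self.cls = nn.Linear(cfg.fc_channels, 2, rng)
        self.reg = nn.Linear(cfg.fc_channels, 4, rng)

    def forward(self, patches):
        x = ops.flatten(patches)
        x = ops.relu(self.fc1(x))
        x = ops.relu(self.fc2(x))
        return self.cls(x), self.reg(x)


class FieldHead(nn.Module):
    """Distance-field regression head.

    Four 3x3 convolutions (as in the mask head), then an upsampling path:
    ``transposed`` uses n transposed 2x2/stride-2 convolutions;``upconv``
    uses n blocks of [2x nearest upsample -> 2x2 conv -> two 3x3 convs].
    Every convolution is followed by batch norm + ReLU except the final
    1x1, which is linear so the regression can reach 0 and 1 symmetrically.
    """

    def __init__(self, cfg: NetConfig, rng):
        super().__init__()
        ch = cfg.head_channels
        self.trunk = []
        cin = cfg.fpn_channels
        for _ in range(4):
            self.trunk.append(nn.Conv2d(cin, ch, 3, rng, bias=False))
            self.trunk.append(nn.BatchNorm2d(ch))
            cin = ch
        self.variant = cfg.upsampling_variant
        self.ups = []
        for _ in range(cfg.n_upsamplings):
            if self.variant == "transposed":
                self.ups.append([nn.ConvTranspose2x2(ch, ch, rng, bias=False),
                                 nn.BatchNorm2d(ch)])
            else:
                self.ups.append([
                    nn.Conv2d(ch, ch, 2, rng, bias=False), nn.BatchNorm2d(ch),
                    nn.Conv2d(ch, ch, 3, rng, bias=False), nn.BatchNorm2d(ch),
                    nn.Conv2d(ch, ch, 3, rng, bias=False), nn.BatchNorm2d(ch),
                ])
        self.final = nn.Conv2d(ch, 1, 1, rng)

    def named_children(self):
        yield from super().named_children()
        for i, group in enumerate(self.ups):
            for j, m in enumerate(group):
                yield f"ups.{i}.{j}", m

    def forward(self, patches):
        x = patches
        for i in range(0, len(self.trunk), 2):
            x = ops.relu(self.trunk[i + 1](self.trunk[i](x)))
        for group in self.ups:
            if self.variant == "transposed":
                x = ops.relu(group[1](group[0](x)))
            else:
                x = ops.upsample2x(x)
                for j in range(0, 6, 2):
                    x = ops.relu(group[j + 1](group[j](x)))
        return self.final(x)  # (n, 1, S, S), linear activation


# ---------------------------------------------------------------------------
# full model


class MaskR2CNN(nn.Module):
    """End-to-end head detector and distance-field regressor."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.body = ResNetBody(cfg, rng)
        self.fpn = FPN(self.body.out_channels, cfg.fpn_channels, rng)
        self.rpn = RPNHead(cfg.fpn_channels, len(cfg.anchor_ratios), rng)
        self.classbox = ClassBoxHead(cfg, rng) if cfg.include_class_head else None
        self.fieldhead = FieldHead(cfg, rng)
        self._anchor_cache = {}

    # -- pieces ---------------------------------------------------------
    def prepare_image(self, image: np.ndarray) -> Tensor:
        """Normalize a [0, 1] grayscale image to a (1, C, H, W) tensor."""
        x = np.asarray(image, dtype=np.float32)
        if x.ndim != 2:
            raise ValueError("expected a 2-D grayscale image")
        if x.shape[0] % 64 or x.shape[1] % 64:
            raise ConfigError("input size must be divisible by 64")
        x = (x - 0.5)[None, None]
        if self.cfg.in_channels == 3:
            x = np.repeat(x, 3, axis=1)
        return Tensor(x)

    def build_feature_pyramid(self, x: Tensor):
        return self.fpn(self.body(x))

    def anchors_for(self, image_size: int) -> np.ndarray:
        if image_size not in self._anchor_cache:
            shapes = [(image_size // s, image_size // s) for s in FPN_STRIDES]
            self._anchor_cache[image_size] = generate_anchors(self.cfg, shapes)
        return self._anchor_cache[image_size]

    def roi_align_patches(self, pyramid, rois: np.ndarray, d: int | None = None) -> Tensor:
        """Multi-level ROI align; output order matches input ROI order."""
        d = d or self.cfg.roi_size
        rois = np.asarray(rois, dtype=np.float64)
        if np.any((rois[:, 2] - rois[:, 0]) <= 0) or np.any((rois[:, 3] - rois[:, 1]) <= 0):
            raise ValueError("zero-area ROI")
        levels = assign_fpn_levels(rois)
        parts, owners = [], []
        for k in range(2, 6):
            sel = np.nonzero(levels == k)[0]
            if sel.size == 0:
                continue
            parts.append(ops.roi_align(pyramid[k - 2], rois[sel], d,
                                       1.0 / FPN_STRIDES[k - 2]))
            owners.append(sel)
        patches = ops.concat_rows(parts)
        order = np.concatenate(owners)
        inv = np.empty_like(order)
        inv[order] = np.arange(order.size)
        return ops.index_rows(patches, inv)

    # -- inference -------------------------------------------------------
    def full_forward(self, image: np.ndarray, max_detections: int = 10):
        """Detect heads and regress their field patches (eval mode)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                dets = self._detect(image, max_detections)
        finally:
            self.train(was_training)
        return dets

    def _detect(self, image, max_detections):
        cfg = self.cfg
        size = image.shape[0]
        x = self.prepare_image(image)
        pyramid = self.build_feature_pyramid(x)
        logits, deltas = self.rpn(pyramid)
        obj = 1.0 / (1.0 + np.exp(-logits.data.astype(np.float64)))
        anchors = self.anchors_for(size)
        props, pscores = propose_rois(anchors, obj, deltas.data,
                                      cfg.rpn_nms_thresh, cfg.pre_nms_test,
                                      cfg.post_nms_test, size)
        if props.shape[0] == 0:
            return []
        if self.classbox is not None:
            patches = self.roi_align_patches(pyramid, props)
            cls_logits, box_deltas = self.classbox(patches)
            z = cls_logits.data - cls_logits.data.max(axis=1, keepdims=True)
            e = np.exp(z)
            prob = (e / e.sum(axis=1, keepdims=True))[:, 1]
            refined = B.clip_boxes(B.decode_deltas(box_deltas.data, props), size)
            scores = prob
        else:
            refined, scores = props, pscores
        keep = scores >= cfg.score_thresh
        if not keep.any():
            return []
        refined, scores = refined[keep], scores[keep]
        wh = (refined[:, 2] - refined[:, 0]) * (refined[:, 3] - refined[:, 1])
        ok = wh > 1.0
        refined, scores = refined[ok], scores[ok]
        if refined.shape[0] == 0:
            return []
        kept = B.nms(refined, scores, cfg.det_nms_thresh)[:max_detections]
        refined, scores = refined[kept], scores[kept]
        fpatches = self.fieldhead(self.roi_align_patches(pyramid, refined))
        out = []
        for i in range(refined.shape[0]):
            patch = np.clip(fpatches.data[i, 0], 0.0, 1.0)
            out.append(Detection(
                box=BBox(*refined[i]), score=float(scores[i]), cls="head",
                field_patch=patch))
        out.sort(key=lambda d: -d.score)
        return out
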