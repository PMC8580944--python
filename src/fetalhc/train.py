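"""Losses, target assignment, augmentation and the staged training schedule.

Training minimizes the multi-task loss ``L = a*L_cls + b*L_box + c*L_df``
(head classification cross-entropy, head box smooth-L1 on positives, and
per-ROI field RMSE), with the RPN's own two losses added to the optimized
total as in standard Mask-RCNN. ``L`` is what is logged and used for
best-model selection. The schedule has three stages: (1) everything except
the residual body, (2) the distance-field head alone — its loss drops more
slowly than the detection losses — and (3) the full network. The optimizer
is plain SGD with momentum at unit batch size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import boxes as B
from .data import Sample
from .errors import ConfigError, EmptyAnnotationError
from .net import MaskR2CNN, NetConfig, propose_rois
from .nn import SGD, ops
from .nn.tensor import Tensor, no_grad
from .targets import BBox, field_bbox

__all__ = [
    "TrainConfig", "LossBreakdown", "ROITargets", "Checkpoint",
    "assign_targets", "rpn_targets", "field_rmse", "total_loss",
    "augment_sample", "train_step", "staged_training", "select_best",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and augmentation settings.

    ``alpha``, ``beta``, ``gamma`` weight the classification, box and field
    terms of the multi-task loss (all 1 by default). ``stage_epochs`` gives
    the lengths of the three freezing stages. Batch size is fixed at one
    image; all randomness (initialization, ROI sampling, augmentation)
    derives from ``seed``.
    """

    lr: float = 1e-3
    momentum: float = 0.9
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    stage_epochs: tuple = (50, 50, 50)
    seed: int = 0
    augment: bool = True
    scale_range: tuple = (0.9, 1.1)
    translate_frac: float = 0.05
    rotate_deg: float = 15.0
    shear_deg: float = 8.0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ConfigError("loss weights must be nonnegative")
        if any(e < 0 for e in self.stage_epochs) or len(self.stage_epochs) != 3:
            raise ConfigError("stage_epochs must be three nonnegative ints")


@dataclass(frozen=True)
class LossBreakdown:
    """Per-step loss components. ``L = alpha*L_cls + beta*L_box + gamma*L_df``;
    the RPN terms are tracked separately and excluded from the identity."""

    L: float
    L_cls: float
    L_box: float
    L_df: float
    rpn_cls: float = 0.0
    rpn_box: float = 0.0


@dataclass
class ROITargets:
    """Sampled training ROIs with class labels, box-delta targets for the
    positives, and field patches cropped+resized to head output size."""

    rois: np.ndarray          # (n, 4)
    labels: np.ndarray        # (n,) 1 = head, 0 = background
    pos_idx: np.ndarray       # indices into rois
    box_deltas: np.ndarray    # (n_pos, 4)
    field_patches: np.ndarray  # (n_pos, 1, S, S)


@dataclass
class Checkpoint:
    stage: str
    epoch: int
    state: dict
    train_loss: float
    val_loss: float


def total_loss(parts, cfg: TrainConfig, include_class: bool = True) -> LossBreakdown:
    """Combine component losses into the logged multi-task loss."""
    l_cls, l_box, l_df = (float(v) for v in parts[:3])
    rpn_cls, rpn_box = (float(v) for v in parts[3:5]) if len(parts) > 3 else (0.0, 0.0)
    if not include_class:
        l_cls = 0.0
    L = cfg.alpha * l_cls + cfg.beta * l_box + cfg.gamma * l_df
    return LossBreakdown(L=L, L_cls=l_cls, L_box=l_box, L_df=l_df,
                         rpn_cls=rpn_cls, rpn_box=rpn_box)


def field_rmse(pred: np.ndarray, target: np.ndarray) -> float:
    """Root-mean-square error between two equal-shape field patches."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    return float(np.sqrt(np.mean((pred - target) ** 2)))


# ---------------------------------------------------------------------------
# target assignment


def rpn_targets(anchors: np.ndarray, gt_box: BBox, cfg: NetConfig,
                rng: np.random.Generator):
    """Anchor labels (1 pos / 0 neg / -1 ignore) and positive delta targets."""
    gt = gt_box.as_array()[None, :]
    iou = B.iou_matrix(anchors, gt)[:, 0]
    labels = np.full(anchors.shape[0], -1, dtype=np.int64)
    labels[iou < cfg.rpn_neg_iou] = 0
    labels[iou >= cfg.rpn_pos_iou] = 1
    labels[int(np.argmax(iou))] = 1  # best anchor is always positive
    pos = np.nonzero(labels == 1)[0]
    neg = np.nonzero(labels == 0)[0]
    n_pos = min(len(pos), cfg.rpn_train_anchors // 2)
    if len(pos) > n_pos:
        off = rng.choice(len(pos), size=len(pos) - n_pos, replace=False)
        labels[pos[off]] = -1
        pos = np.nonzero(labels == 1)[0]
    n_neg = min(len(neg), cfg.rpn_train_anchors - len(pos))
    if len(neg) > n_neg:
        off = rng.choice(len(neg), size=len(neg) - n_neg, replace=False)
        labels[neg[off]] = -1
    deltas = B.encode_deltas(np.repeat(gt, len(pos), axis=0), anchors[pos])
    return labels, pos, deltas


def _crop_resize_field(field: np.ndarray, rois: np.ndarray, out_size: int) -> np.ndarray:
    """Crop the GT field to each ROI and bilinearly resize to out_size^2."""
    t = Tensor(field[None, None].astype(np.float32))
    with no_grad():
        patches = ops.roi_align(t, rois, out_size, spatial_scale=1.0, sampling=1)
    return patches.data


def assign_targets(proposals: np.ndarray, gt_box: BBox, gt_field: np.ndarray,
                   cfg: NetConfig, rng: np.random.Generator,
                   n_rois: int | None = None,
                   include_gt: bool = True) -> ROITargets:
    """Label proposals against the single ground-truth head box and sample
    a fixed number of training ROIs at <= 1:3 positive:negative ratio."""
    if gt_box is None or gt_field is None:
        raise ValueError("ground truth box and field are required")
    n_rois = n_rois or cfg.train_rois_per_image
    props = np.asarray(proposals, dtype=np.float64).reshape(-1, 4)
    if include_gt:
        props = np.concatenate([props, gt_box.as_array()[None, :]], axis=0)
    iou = B.iou_matrix(props, gt_box.as_array()[None, :])[:, 0]
    pos_all = np.nonzero(iou >= cfg.head_pos_iou)[0]
    neg_all = np.nonzero(iou < cfg.head_pos_iou)[0]
    pos_cap = cfg.max_positive_rois or (n_rois // 4)
    n_pos = min(len(pos_all), max(1, min(n_rois // 4, pos_cap)))
    pos = rng.choice(pos_all, size=n_pos, replace=False) if len(pos_all) else pos_all
    n_neg = min(len(neg_all), n_rois - len(pos))
    neg = rng.choice(neg_all, size=n_neg, replace=False) if len(neg_all) else neg_all
    sel = np.concatenate([pos, neg]).astype(np.int64)
    rois = props[sel]
    labels = np.zeros(len(sel), dtype=np.int64)
    labels[:len(pos)] = 1
    pos_idx = np.arange(len(pos))
    gt = np.repeat(gt_box.as_array()[None, :], len(pos), axis=0)
    box_deltas = B.encode_deltas(gt, rois[:len(pos)]) if len(pos) else np.zeros((0, 4))
    S = cfg.field_patch_size
    if len(pos):
        field_patches = _crop_resize_field(gt_field, rois[:len(pos)], S)
    else:
        field_patches = np.zeros((0, 1, S, S), dtype=np.float32)
    return ROITargets(rois=rois, labels=labels, pos_idx=pos_idx,
                      box_deltas=box_deltas, field_patches=field_patches)


# ---------------------------------------------------------------------------
# augmentation


def _affine_matrix(scale, angle, shear, center):
    ca, sa = math.cos(angle), math.sin(angle)
    sh = math.tan(shear)
    # rotate * shear * isotropic scale, about the image center
    m = np.array([[ca, -sa], [sa, ca]]) @ np.array([[1.0, sh], [0.0, 1.0]]) * scale
    return m


def augment_sample(sample: Sample, rng: np.random.Generator,
                   cfg: TrainConfig) -> Sample:
    """One random affine perturbation applied consistently to image and
    field; the box is recomputed from the warped field. If the transform
    pushes the head (the field peak) out of the canvas the draw is retried
    up to 10 times, after which the sample is returned unaugmented."""
    h, w = sample.image.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    for _ in range(10):
        scale = rng.uniform(*cfg.scale_range)
        angle = math.radians(rng.uniform(-cfg.rotate_deg, cfg.rotate_deg))
        shear = math.radians(rng.uniform(-cfg.shear_deg, cfg.shear_deg))
        tr = rng.uniform(-cfg.translate_frac, cfg.translate_frac, size=2) * h
        if scale == 1.0 and angle == 0.0 and shear == 0.0 and not tr.any():
            return sample
        m = _affine_matrix(scale, angle, shear, center)
        # scipy maps output coords to input: x_in = inv(m) @ (x_out - c - t) + c
        minv = np.linalg.inv(m)
        offset = center - minv @ (center + tr)  # tr is a (row, col) shift
        img = ndimage.affine_transform(sample.image, minv, offset=offset,
                                       order=1, mode="constant", cval=0.0,
                                       output=np.float32)
        fld = ndimage.affine_transform(sample.field, minv, offset=offset,
                                       order=1, mode="constant", cval=0.0,
                                       output=np.float32)
        if fld.max() < 0.5:
            continue  # head essentially gone; retry
        try:
            box = field_bbox(fld)
        except EmptyAnnotationError:
            continue
        return replace_sample(sample, image=img, field=fld, box=box)
    return sample


def replace_sample(s: Sample, **kw) -> Sample:
    from dataclasses import replace as dc_replace
    kw.setdefault("ellipse_net", None)  # stale after warping
    return dc_replace(s, **kw)


# ---------------------------------------------------------------------------
# one optimization step


def train_step(model: MaskR2CNN, sample: Sample, tcfg: TrainConfig,
               rng: np.random.Generator, optimizer: SGD | None = None) -> LossBreakdown:
    """Forward, loss, and (if an optimizer is given) backward + update."""
    cfg = model.cfg
    size = sample.image.shape[0]
    x = model.prepare_image(sample.image)
    pyramid = model.build_feature_pyramid(x)
    logits, deltas = model.rpn(pyramid)
    anchors = model.anchors_for(size)

    # RPN losses on a sampled anchor minibatch
    labels, pos, rpn_delta_t = rpn_targets(anchors, sample.box, cfg, rng)
    train_ids = np.nonzero(labels >= 0)[0]
    rpn_cls = ops.bce_with_logits(ops.index_rows(logits, train_ids),
                                  labels[train_ids])
    if len(pos):
        rpn_box = ops.smooth_l1(ops.index_rows(deltas, pos), rpn_delta_t)
    else:
        rpn_box = Tensor(np.float32(0.0))

    # proposals (no gradient through box coordinates)
    obj = 1.0 / (1.0 + np.exp(-logits.data.astype(np.float64)))
    props, _ = propose_rois(anchors, obj, deltas.data, cfg.rpn_nms_thresh,
                            cfg.pre_nms_train, cfg.post_nms_train, size)
    tgt = assign_targets(props, sample.box, sample.field, cfg, rng)

    n_pos = len(tgt.pos_idx)
    if cfg.include_class_head:
        patches = model.roi_align_patches(pyramid, tgt.rois)
        cls_logits, box_pred = model.classbox(patches)
        l_cls = ops.softmax_cross_entropy(cls_logits, tgt.labels)
        if n_pos:
            l_box = ops.smooth_l1(ops.index_rows(box_pred, tgt.pos_idx),
                                  tgt.box_deltas)
        else:
            l_box = Tensor(np.float32(0.0))
    else:
        l_cls = Tensor(np.float32(0.0))
        l_box = Tensor(np.float32(0.0))

    if n_pos:
        pos_patches = model.roi_align_patches(pyramid, tgt.rois[tgt.pos_idx])
        pred_fields = model.fieldhead(pos_patches)
        l_df = ops.field_rmse_loss(pred_fields, tgt.field_patches)
    else:
        l_df = Tensor(np.float32(0.0))

    if optimizer is not None:
        terms = []
        for weight, t in ((tcfg.alpha, l_cls), (tcfg.beta, l_box),
                          (tcfg.gamma, l_df), (1.0, rpn_cls), (1.0, rpn_box)):
            if weight and t.requires_grad:
                terms.append((weight, t))
        optimizer.zero_grad()
        for weight, t in terms:
            t.backward(np.float32(weight))
        optimizer.step()

    return total_loss((l_cls.item(), l_box.item(), l_df.item(),
                       rpn_cls.item(), rpn_box.item()), tcfg,
                      include_class=cfg.include_class_head)


def _validation_loss(model: MaskR2CNN, val_set, tcfg: TrainConfig,
                     seed: int) -> float:
    """Mean multi-task L over the validation set, without augmentation."""
    if not val_set:
        return float("nan")
    was = model.training
    model.eval()
    rng = np.random.default_rng(seed)
    tot = 0.0
    with no_grad():
        for s in val_set:
            tot += train_step(model, s, tcfg, rng, optimizer=None).L
    model.train(was)
    return tot / len(val_set)


# ---------------------------------------------------------------------------
# staged schedule


def _set_stage_freezing(model: MaskR2CNN, stage: str):
    model.freeze(False)
    if stage == "heads":
        model.body.freeze(True)
    elif stage == "df":
        model.freeze(True)
        model.fieldhead.freeze(False)
    elif stage == "all":
        pass
    else:  # pragma: no cover
        raise ConfigError(f"unknown stage {stage!r}")


def staged_training(dataset, val_set, net_cfg: NetConfig,
                    train_cfg: TrainConfig, model: MaskR2CNN | None = None,
                    log: list | None = None):
    """Run the three freezing stages and return (model, checkpoints).

    One checkpoint (full state dict + train/validation L) is recorded per
    epoch; an initialization checkpoint is always present so a zero-epoch
    schedule still returns something selectable.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    if model is None:
        model = MaskR2CNN(net_cfg, seed=train_cfg.seed)
    rng = np.random.default_rng((train_cfg.seed * 2654435761 + 17) % (2 ** 31))
    checkpoints = [Checkpoint(
        stage="init", epoch=0, state=model.state_dict(),
        train_loss=float("nan"),
        val_loss=_validation_loss(model, val_set, train_cfg, train_cfg.seed + 9))]
    stages = (("heads", train_cfg.stage_epochs[0]),
              ("df", train_cfg.stage_epochs[1]),
              ("all", train_cfg.stage_epochs[2]))
    model.train()
    for stage, n_epochs in stages:
        if n_epochs == 0:
            continue
        _set_stage_freezing(model, stage)
        opt = SGD(model.parameters(), lr=train_cfg.lr,
                  momentum=train_cfg.momentum)
        for epoch in range(1, n_epochs + 1):
            order = rng.permutation(len(dataset))
            tot = 0.0
            for i in order:
                s = dataset[i]
                if train_cfg.augment:
                    s = augment_sample(s, rng, train_cfg)
                br = train_step(model, s, train_cfg, rng, optimizer=opt)
                if log is not None:
                    log.append((stage, epoch, br))
                tot += br.L
            val_l = _validation_loss(model, val_set, train_cfg,
                                     train_cfg.seed + 9)
            checkpoints.append(Checkpoint(
                stage=stage, epoch=epoch, state=model.state_dict(),
                train_loss=tot / len(dataset), val_loss=val_l))
    return model, checkpoints


def select_best(checkpoints, val_losses=None) -> Checkpoint:
    """Checkpoint with the lowest validation L; ties go to the earliest."""
    if not checkpoints:
        raise ValueError("no checkpoints")
    if val_losses is None:
        val_losses = [c.val_loss for c in checkpoints]
    best, best_l = None, math.inf
    for c, l in zip(checkpoints, val_losses):
        if not math.isnan(l) and l < best_l:
            best, best_l = c, l
    return best if best is not None else checkpoints[0]
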