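"""Train the detector-regressor on a handful of phantoms (CPU, ~1 min).

Runs a miniature version of the three-stage schedule — (1) heads with the
residual body frozen, (2) the distance-field head alone, (3) everything —
and prints the loss trace. Real desk-scale experiments use 200 phantoms
and 5+5+5 epochs; this is a smoke-scale demonstration of the same loop.
"""

from fetalhc.net import NetConfig
from fetalhc.synth import PhantomConfig, synthetic_samples
from fetalhc.train import TrainConfig, select_best, staged_training

train_set, _ = synthetic_samples(12, PhantomConfig.desk(seed=1))
val_set, _ = synthetic_samples(4, PhantomConfig.desk(seed=2))

net_cfg = NetConfig(image_size=128, backbone_depth=18, width_mult=0.125,
                    fpn_channels=16, head_channels=16, fc_channels=64,
                    roi_size=7, anchor_scales=(16, 32, 64, 128, 256),
                    train_rois_per_image=64, pre_nms_train=1000,
                    post_nms_train=100, pre_nms_test=500, post_nms_test=50)
train_cfg = TrainConfig(stage_epochs=(1, 1, 1), seed=0)

model, checkpoints = staged_training(train_set, val_set, net_cfg, train_cfg)
for c in checkpoints:
    print(f"stage {c.stage:5s} epoch {c.epoch}: "
          f"train L {c.train_loss:.3f}  val L {c.val_loss:.3f}")
best = select_best(checkpoints)
print(f"selected: stage {best.stage} epoch {best.epoch} "
      f"(lowest validation L = {best.val_loss:.3f})")
print("L = L_cls + L_box + L_df; the RPN trains jointly with its own losses")
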