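import numpy as np
import pytest

from fetalhc.net import NetConfig
from fetalhc.synth import PhantomConfig, synthetic_samples


def desk_net_config(**overrides) -> NetConfig:
    """Reduced network sized for single-CPU tests: ResNet-18 body at 3/16
    width, 20-channel FPN, 12-channel field head, 128 px inputs, d=7, u=3."""
    kw = dict(image_size=128, backbone_depth=18, width_mult=0.1875,
              fpn_channels=20, head_channels=12, fc_channels=80,
              roi_size=7, anchor_scales=(16, 32, 64, 128, 256),
              train_rois_per_image=64, pre_nms_train=1000,
              post_nms_train=100, pre_nms_test=500, post_nms_test=50)
    kw.update(overrides)
    return NetConfig(**kw)


@pytest.fixture(scope="session")
def desk_cfg():
    return desk_net_config()


@pytest.fixture(scope="session")
def phantom_cfg():
    return PhantomConfig.desk(seed=5)


@pytest.fixture(scope="session")
def small_samples(phantom_cfg):
    samples, _ = synthetic_samples(6, phantom_cfg)
    return samples


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
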