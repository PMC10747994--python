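import numpy as np
import pytest

from abfp.attention import ChannelAttentionParams, SpatialAttentionParams
from abfp.synthetic import make_pyramid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_pyramid():
    return make_pyramid(3, 4, (16, 16), seed=7)


@pytest.fixture
def attention_params():
    cap = ChannelAttentionParams.init(4, reduction_ratio=2, seed=11)
    sap = SpatialAttentionParams.init(seed=12)
    return cap, sap


def zero_channel_params(channels: int, r: int = 1) -> ChannelAttentionParams:
    c_mid = channels // r
    return ChannelAttentionParams(
        w0=np.zeros((c_mid, channels), dtype=np.float32),
        b0=np.zeros(c_mid, dtype=np.float32),
        w1=np.zeros((channels, c_mid), dtype=np.float32),
        b1=np.zeros(channels, dtype=np.float32),
        reduction_ratio=r,
    )


def zero_spatial_params() -> SpatialAttentionParams:
    return SpatialAttentionParams(
        kernel=np.zeros((1, 2, 7, 7), dtype=np.float32),
        bias=np.zeros(1, dtype=np.float32),
    )
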