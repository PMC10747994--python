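"""Detector necks: a baseline top-down FPN and the attention-balanced neck.

``fpn_forward`` is the standard feature pyramid network: 1x1 lateral
convolutions project each backbone level to a common width, a top-down
pathway adds nearest-neighbour-upsampled coarser maps, and 3x3 output
convolutions smooth the result.

``abfp_forward`` stacks the attention-balanced refinement on any
uniform-channel pyramid (FPN outputs in the reference configuration):
integrate all levels into the balanced semantic map, refine it with the
parallel channel/spatial attention gates (or a plain 3x3 convolution in the
attention-off ablation arm), and strengthen every level by adding the
rescaled refined map.  The operation preserves every level's shape, which
is what makes it stackable on FPN, PAFPN or BiFPN outputs alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .autodiff import Tensor, astensor, conv2d
from .pyramid import FeaturePyramid, integrate, strengthen
from .attention import (
    ChannelAttentionParams,
    SpatialAttentionParams,
    abfp_refine,
    _kaiming_uniform,
)

__all__ = [
    "NeckConfig",
    "FPNParams",
    "ABFPParams",
    "fpn_forward",
    "abfp_forward",
    "abfp_extra_param_count",
]


@dataclass
class NeckConfig:
    """Configuration shared by the FPN and the ABFP refinement.

    Defaults mirror the reference detector: four backbone stages feeding an
    FPN of width ``out_channels``; the balanced map lives at the coarser of
    the two middle levels (index ``N // 2``).
    """

    in_channels: list[int] = field(default_factory=lambda: [256, 512, 1024, 2048])
    out_channels: int = 256
    intermediate_index: int | None = None  # None -> N // 2
    attention: bool = True
    reduction_ratio: int = 16
    upsample_mode: str = "nearest"
    attention_bias: bool = True

    def __post_init__(self):
        if self.out_channels <= 0:
            raise ValueError("out_channels must be positive")
        if len(self.in_channels) < 2:
            raise ValueError("a pyramid neck needs at least two levels")
        if self.upsample_mode not in ("nearest", "bilinear"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")

    @property
    def num_levels(self) -> int:
        return len(self.in_channels)

    def resolved_intermediate_index(self) -> int:
        return self.num_levels // 2 if self.intermediate_index is None else self.intermediate_index

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NeckConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _conv(x, w, b, stride=1, pad=0):
    """conv2d that accepts unbatched C x H x W input."""
    xt = astensor(x)
    if xt.ndim == 3:
        out = conv2d(xt.reshape(1, *xt.shape), w, b, stride=stride, pad=pad)
        return out.reshape(*out.shape[1:])
    return conv2d(xt, w, b, stride=stride, pad=pad)


@dataclass
class FPNParams:
    """Per-level 1x1 lateral and 3x3 output convolution weights."""

    lateral_w: list  # (out, in_l, 1, 1)
    lateral_b: list  # (out,)
    output_w: list  # (out, out, 3, 3)
    output_b: list  # (out,)

    @classmethod
    def init(cls, cfg: NeckConfig, seed: int | np.random.Generator = 0) -> "FPNParams":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        co = cfg.out_channels
        lw, lb, ow, ob = [], [], [], []
        for ci in cfg.in_channels:
            lw.append(_kaiming_uniform(rng, (co, ci, 1, 1), ci))
            lb.append(np.zeros(co, dtype=np.float32))
            ow.append(_kaiming_uniform(rng, (co, co, 3, 3), co * 9))
            ob.append(np.zeros(co, dtype=np.float32))
        return cls(lw, lb, ow, ob)

    def num_params(self) -> int:
        arrays = self.lateral_w + self.lateral_b + self.output_w + self.output_b
        return sum(a.data.size if isinstance(a, Tensor) else a.size for a in arrays)


def _upsample_to(t: Tensor, hw, mode: str) -> Tensor:
    from .pyramid import rescale_to_level

    if mode == "nearest":
        return rescale_to_level(t, hw, "up")
    # bilinear: differentiable composition of two nearest-style gathers with
    # linear weights along each axis
    return _bilinear_resize(t, hw)


def _bilinear_resize(t: Tensor, hw) -> Tensor:
    from .autodiff import gather_hw

    h_in, w_in = t.shape[-2:]
    h_out, w_out = int(hw[0]), int(hw[1])
    ys = (np.arange(h_out) + 0.5) * h_in / h_out - 0.5
    xs = (np.arange(w_out) + 0.5) * w_in / w_out - 0.5
    y0 = np.clip(np.floor(ys).astype(np.intp), 0, h_in - 1)
    x0 = np.clip(np.floor(xs).astype(np.intp), 0, w_in - 1)
    y1 = np.clip(y0 + 1, 0, h_in - 1)
    x1 = np.clip(x0 + 1, 0, w_in - 1)
    wy = np.clip(ys - y0, 0.0, 1.0).astype(np.float32)
    wx = np.clip(xs - x0, 0.0, 1.0).astype(np.float32)
    wy_col = wy[:, None]
    wx_row = wx[None, :]
    tl = gather_hw(t, y0, x0)
    tr = gather_hw(t, y0, x1)
    bl = gather_hw(t, y1, x0)
    br = gather_hw(t, y1, x1)
    top = tl * (1.0 - wx_row) + tr * wx_row
    bot = bl * (1.0 - wx_row) + br * wx_row
    return top * (1.0 - wy_col) + bot * wy_col


def fpn_forward(backbone_features: FeaturePyramid, cfg: NeckConfig,
                params: FPNParams) -> FeaturePyramid:
    """Standard top-down FPN over backbone features with per-level channel counts."""
    n = backbone_features.num_levels
    if n != cfg.num_levels:
        raise ValueError(f"pyramid has {n} levels but config expects {cfg.num_levels}")
    counts = backbone_features.channel_counts()
    if counts != list(cfg.in_channels):
        raise ValueError(f"channel counts {counts} do not match config {cfg.in_channels}")
    tensors = [astensor(l) for l in backbone_features.levels]
    laterals = [
        _conv(t, astensor(params.lateral_w[i]), astensor(params.lateral_b[i]))
        for i, t in enumerate(tensors)
    ]
    merged = [None] * n
    merged[n - 1] = laterals[n - 1]
    for i in range(n - 2, -1, -1):
        up = _upsample_to(merged[i + 1], laterals[i].shape[-2:], cfg.upsample_mode)
        merged[i] = laterals[i] + up
    outputs = [
        _conv(m, astensor(params.output_w[i]), astensor(params.output_b[i]), pad=1)
        for i, m in enumerate(merged)
    ]
    if not any(isinstance(l, Tensor) for l in backbone_features.levels):
        outputs = [o.data for o in outputs]
    return FeaturePyramid(levels=outputs, level_names=list(backbone_features.level_names))


@dataclass
class ABFPParams:
    """Parameters of the refinement stage: attention gates, or a 3x3 conv ablation."""

    channel: ChannelAttentionParams | None
    spatial: SpatialAttentionParams | None
    refine_w: object | None = None  # (C, C, 3, 3), used when attention is off
    refine_b: object | None = None

    @classmethod
    def init(cls, cfg: NeckConfig, seed: int | np.random.Generator = 0) -> "ABFPParams":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        c = cfg.out_channels
        if cfg.attention:
            return cls(
                channel=ChannelAttentionParams.init(
                    c, cfg.reduction_ratio, bias=cfg.attention_bias, seed=rng
                ),
                spatial=SpatialAttentionParams.init(bias=cfg.attention_bias, seed=rng),
            )
        return cls(
            channel=None,
            spatial=None,
            refine_w=_kaiming_uniform(rng, (c, c, 3, 3), c * 9),
            refine_b=np.zeros(c, dtype=np.float32),
        )

    def num_params(self) -> int:
        n = 0
        if self.channel is not None:
            n += self.channel.num_params()
        if self.spatial is not None:
            n += self.spatial.num_params()
        for a in (self.refine_w, self.refine_b):
            if a is not None:
                n += a.data.size if isinstance(a, Tensor) else a.size
        return n


def abfp_extra_param_count(channels: int, reduction_ratio: int, attention: bool = True,
                           bias: bool = True) -> int:
    """Closed-form parameter count of the refinement stage.

    Attention on: shared MLP ``2 * C * (C // r)`` (+ ``C // r + C`` biases)
    plus the 7x7 two-plane conv ``7 * 7 * 2`` (+ 1 bias).
    Attention off: one 3x3 conv ``C * C * 9`` (+ ``C`` bias).
    """
    if attention:
        c_mid = channels // reduction_ratio
        n = 2 * channels * c_mid + 2 * 7 * 7
        if bias:
            n += c_mid + channels + 1
        return n
    n = channels * channels * 9
    if bias:
        n += channels
    return n


def abfp_forward(fpn_outputs: FeaturePyramid, cfg: NeckConfig,
                 params: ABFPParams) -> FeaturePyramid:
    """Integrate -> refine -> strengthen over a uniform-channel pyramid."""
    counts = fpn_outputs.channel_counts()
    if len(set(counts)) != 1:
        raise ValueError(f"abfp_forward requires a uniform channel count, got {counts}")
    idx = cfg.resolved_intermediate_index()
    balanced = integrate(fpn_outputs, idx)
    if cfg.attention:
        refined = abfp_refine(balanced, params.channel, params.spatial)
    else:
        refined_map = _conv(
            balanced.map, astensor(params.refine_w), astensor(params.refine_b), pad=1
        )
        if not isinstance(balanced.map, Tensor):
            refined_map = refined_map.data
        refined = type(balanced)(map=refined_map, source_level_index=idx)
    return strengthen(fpn_outputs, refined)
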