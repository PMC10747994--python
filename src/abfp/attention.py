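"""Channel and spatial attention gates and their parallel-additive composition.

The refinement applied to the balanced semantic map ``F_b`` is

    F_ab = (M_c(F_b) * F_b) + (M_s(F_b) * F_b)

where ``M_c`` is a per-channel sigmoid gate from a shared two-layer MLP over
globally average- and max-pooled channel descriptors,

    M_c(F) = sigmoid( W1 relu(W0 avgpool(F)) + W1 relu(W0 maxpool(F)) ),

and ``M_s`` is a per-pixel sigmoid gate from a 7x7 convolution over the
channel-wise average and max planes,

    M_s(F) = sigmoid( f_7x7([avg_c(F); max_c(F)]) ).

The two branches act on ``F_b`` in PARALLEL and their gated copies are
summed — unlike the sequential composition of the standard CBAM block.  No
normalisation follows the sum, so outputs may reach twice the input
magnitude (each gate is strictly below 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor, concat, conv2d
from .pyramid import BalancedSemanticMap

__all__ = [
    "ChannelAttentionParams",
    "SpatialAttentionParams",
    "AttentionMap",
    "channel_attention",
    "spatial_attention",
    "abfp_refine",
    "save_params",
    "load_params",
]


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


@dataclass
class ChannelAttentionParams:
    """Shared-MLP weights for the channel gate.

    ``w0`` maps C -> C//r, ``w1`` maps C//r -> C; the same MLP serves both
    the average-pooled and the max-pooled descriptor.  ``r`` is the
    reduction ratio (clamped so the bottleneck keeps at least one unit).
    """

    w0: np.ndarray
    b0: np.ndarray | None
    w1: np.ndarray
    b1: np.ndarray | None
    reduction_ratio: int

    def __post_init__(self):
        c_mid, c = np.asarray(self.w0.data if isinstance(self.w0, Tensor) else self.w0).shape
        if c % self.reduction_ratio != 0:
            raise ValueError(
                f"reduction ratio {self.reduction_ratio} must divide channel count {c}"
            )
        if c // self.reduction_ratio != c_mid:
            raise ValueError("w0 shape inconsistent with reduction ratio")

    @property
    def channels(self) -> int:
        w = self.w0.data if isinstance(self.w0, Tensor) else self.w0
        return w.shape[1]

    @classmethod
    def init(cls, channels: int, reduction_ratio: int = 16, bias: bool = True,
             seed: int | np.random.Generator = 0) -> "ChannelAttentionParams":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        r = max(1, min(reduction_ratio, channels))
        while channels % r != 0:  # keep r a divisor so C/r is integral
            r -= 1
        c_mid = channels // r
        return cls(
            w0=_kaiming_uniform(rng, (c_mid, channels), channels),
            b0=np.zeros(c_mid, dtype=np.float32) if bias else None,
            w1=_kaiming_uniform(rng, (channels, c_mid), c_mid),
            b1=np.zeros(channels, dtype=np.float32) if bias else None,
            reduction_ratio=r,
        )

    def num_params(self) -> int:
        n = self.w0.size + self.w1.size if not isinstance(self.w0, Tensor) else (
            self.w0.data.size + self.w1.data.size
        )
        for b in (self.b0, self.b1):
            if b is not None:
                n += b.data.size if isinstance(b, Tensor) else b.size
        return n


@dataclass
class SpatialAttentionParams:
    """7x7 convolution over the stacked [avg; max] channel-statistic planes."""

    kernel: np.ndarray  # (1, 2, 7, 7)
    bias: np.ndarray | None  # scalar, shape (1,)

    def __post_init__(self):
        k = self.kernel.data if isinstance(self.kernel, Tensor) else self.kernel
        if tuple(k.shape) != (1, 2, 7, 7):
            raise ValueError(f"spatial kernel must be (1, 2, 7, 7), got {k.shape}")

    @classmethod
    def init(cls, bias: bool = True,
             seed: int | np.random.Generator = 0) -> "SpatialAttentionParams":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return cls(
            kernel=_kaiming_uniform(rng, (1, 2, 7, 7), 2 * 7 * 7),
            bias=np.zeros(1, dtype=np.float32) if bias else None,
        )

    def num_params(self) -> int:
        k = self.kernel.data if isinstance(self.kernel, Tensor) else self.kernel
        n = k.size
        if self.bias is not None:
            n += self.bias.data.size if isinstance(self.bias, Tensor) else self.bias.size
        return n


@dataclass
class AttentionMap:
    """A sigmoid gate: length-C vector (channel) or H x W grid (spatial)."""

    kind: str  # "channel" | "spatial"
    values: object  # ndarray or Tensor

    @property
    def data(self) -> np.ndarray:
        return self.values.data if isinstance(self.values, Tensor) else np.asarray(self.values)


def _mlp(x: Tensor, p: ChannelAttentionParams) -> Tensor:
    # x has shape (..., C); right-multiply by transposed weights so the same
    # code serves single maps and batches
    h = x @ astensor(p.w0).transpose((1, 0))
    if p.b0 is not None:
        h = h + astensor(p.b0)
    h = h.relu()
    out = h @ astensor(p.w1).transpose((1, 0))
    if p.b1 is not None:
        out = out + astensor(p.b1)
    return out


def _channel_gate_t(f: Tensor, params: ChannelAttentionParams) -> Tensor:
    if f.ndim not in (3, 4):
        raise ValueError(f"expected (B,)C x H x W input, got shape {f.shape}")
    if f.shape[-3] != params.channels:
        raise ValueError(
            f"input has {f.shape[-3]} channels but params expect {params.channels}"
        )
    avg_desc = f.mean(axis=(-2, -1))
    max_desc = f.amax(axis=(-2, -1))
    return (_mlp(avg_desc, params) + _mlp(max_desc, params)).sigmoid()


def channel_attention(f, params: ChannelAttentionParams) -> AttentionMap:
    """Per-channel gate from the shared MLP over avg- and max-pooled descriptors."""
    ft = astensor(f)
    gate = _channel_gate_t(ft, params)
    values = gate if isinstance(f, Tensor) else gate.data
    return AttentionMap(kind="channel", values=values)


def _spatial_gate_t(f: Tensor, params: SpatialAttentionParams) -> Tensor:
    if f.ndim not in (3, 4):
        raise ValueError(f"expected (B,)C x H x W input, got shape {f.shape}")
    avg_plane = f.mean(axis=-3, keepdims=True)
    max_plane = f.amax(axis=-3, keepdims=True)
    stacked = concat([avg_plane, max_plane], axis=-3)  # avg first, then max
    h, w = stacked.shape[-2:]
    batched = stacked if stacked.ndim == 4 else stacked.reshape(1, 2, h, w)
    logits = conv2d(batched, astensor(params.kernel),
                    None if params.bias is None else astensor(params.bias),
                    stride=1, pad=3)
    if f.ndim == 3:
        return logits.reshape(h, w).sigmoid()
    return logits.reshape(f.shape[0], h, w).sigmoid()


def spatial_attention(f, params: SpatialAttentionParams) -> AttentionMap:
    """Per-pixel gate from a zero-padded 7x7 convolution of the [avg; max] planes."""
    ft = astensor(f)
    gate = _spatial_gate_t(ft, params)
    values = gate if isinstance(f, Tensor) else gate.data
    return AttentionMap(kind="spatial", values=values)


def abfp_refine(f_b: BalancedSemanticMap, cap: ChannelAttentionParams,
                sap: SpatialAttentionParams,
                channel_gate=None, spatial_gate=None) -> BalancedSemanticMap:
    """Parallel-additive attention refinement of the balanced semantic map.

    ``channel_gate`` / ``spatial_gate`` allow injecting fixed gates (arrays)
    in place of the computed attention maps — used to verify identities such
    as constant-0.5 gates reproducing the input exactly.
    """
    ft = astensor(f_b.map)
    if ft.ndim not in (3, 4):
        raise ValueError(f"expected (B,)C x H x W balanced map, got shape {ft.shape}")
    m_c = astensor(channel_gate) if channel_gate is not None else _channel_gate_t(ft, cap)
    m_s = astensor(spatial_gate) if spatial_gate is not None else _spatial_gate_t(ft, sap)
    if m_c.shape != ft.shape[:-2]:
        raise ValueError(f"channel gate shape {m_c.shape} != {ft.shape[:-2]}")
    expect_s = ft.shape[:-3] + ft.shape[-2:]
    if m_s.shape != expect_s:
        raise ValueError(f"spatial gate shape {m_s.shape} != {expect_s}")
    refined = m_c.reshape(*m_c.shape, 1, 1) * ft + m_s.reshape(
        *ft.shape[:-3], 1, *ft.shape[-2:]
    ) * ft
    if not isinstance(f_b.map, Tensor):
        refined = refined.data
    return BalancedSemanticMap(map=refined, source_level_index=f_b.source_level_index)


# -- checkpoint IO (flat key -> array archive) --------------------------------

def _flatten(cap: ChannelAttentionParams, sap: SpatialAttentionParams) -> dict:
    out = {
        "channel.w0": cap.w0, "channel.w1": cap.w1,
        "channel.reduction_ratio": np.array(cap.reduction_ratio),
        "spatial.kernel": sap.kernel,
    }
    if cap.b0 is not None:
        out["channel.b0"] = cap.b0
    if cap.b1 is not None:
        out["channel.b1"] = cap.b1
    if sap.bias is not None:
        out["spatial.bias"] = sap.bias
    return out


def save_params(path, cap: ChannelAttentionParams, sap: SpatialAttentionParams) -> None:
    """Write attention parameters to an npz archive with documented flat keys:

    ``channel.w0``, ``channel.b0``, ``channel.w1``, ``channel.b1``,
    ``channel.reduction_ratio``, ``spatial.kernel``, ``spatial.bias``.
    """
    np.savez(path, **_flatten(cap, sap))


def load_params(path) -> tuple[ChannelAttentionParams, SpatialAttentionParams]:
    with np.load(path, allow_pickle=False) as a:
        cap = ChannelAttentionParams(
            w0=a["channel.w0"],
            b0=a["channel.b0"] if "channel.b0" in a else None,
            w1=a["channel.w1"],
            b1=a["channel.b1"] if "channel.b1" in a else None,
            reduction_ratio=int(a["channel.reduction_ratio"]),
        )
        sap = SpatialAttentionParams(
            kernel=a["spatial.kernel"],
            bias=a["spatial.bias"] if "spatial.bias" in a else None,
        )
    return cap, sap
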