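"""Feature-pyramid data model and the balanced-pyramid rescale/integrate/strengthen path.

The balanced feature pyramid (BFP) treats every level of a multi-scale
feature pyramid symmetrically: all levels are rescaled to one intermediate
resolution, averaged into a single *balanced semantic map*

    C_bar = (1/N) * sum_r C_r,

optionally refined (see :mod:`abfp.attention`), and the refined map is
rescaled back to every level's native resolution and added to it.  The
averaging introduces no learned parameters; downscaling uses non-overlapping
max pooling and upscaling uses nearest-neighbour interpolation, so a
constant map survives every rescale exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, astensor, gather_hw

__all__ = [
    "FeaturePyramid",
    "BalancedSemanticMap",
    "rescale_to_level",
    "integrate",
    "strengthen",
]


def _is_tensor_like(levels) -> bool:
    return any(isinstance(x, Tensor) for x in levels)


@dataclass
class FeaturePyramid:
    """Ordered list of feature maps with dyadically decreasing resolution.

    Each level is a ``C x H_l x W_l`` array (a leading batch axis is also
    accepted); consecutive levels satisfy ``H_{l+1} == ceil(H_l / 2)`` and
    likewise for width.  All levels share the channel count ``C`` — the
    precondition for the unweighted balanced mean.
    """

    levels: list
    level_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.levels) < 1:
            raise ValueError("a pyramid needs at least one level")
        if not self.level_names:
            # P2..P{N+1} by convention: P2 is the highest-resolution level
            self.level_names = [f"P{i + 2}" for i in range(len(self.levels))]
        if len(self.level_names) != len(self.levels):
            raise ValueError("level_names must match the number of levels")
        self.validate()

    def validate(self) -> None:
        shapes = [np.asarray(l.data if isinstance(l, Tensor) else l).shape for l in self.levels]
        for s in shapes:
            if len(s) < 3:
                raise ValueError("each level must be at least C x H x W")
            if min(s) == 0:
                raise ValueError("zero-sized feature map")
        for a, b in zip(shapes, shapes[1:]):
            if b[-2] != -(-a[-2] // 2) or b[-1] != -(-a[-1] // 2):
                raise ValueError(
                    f"levels must halve in resolution (ceil): got {a[-2:]} then {b[-2:]}"
                )

    @property
    def num_levels(self) -> int:
        return len(self.levels)

    @property
    def channel_count(self) -> int:
        lvl = self.levels[0]
        return (lvl.data if isinstance(lvl, Tensor) else lvl).shape[-3]

    def channel_counts(self) -> list[int]:
        return [
            (l.data if isinstance(l, Tensor) else np.asarray(l)).shape[-3] for l in self.levels
        ]

    def spatial_shapes(self) -> list[tuple[int, int]]:
        return [
            tuple((l.data if isinstance(l, Tensor) else np.asarray(l)).shape[-2:])
            for l in self.levels
        ]

    def save(self, path) -> None:
        """Serialize to an npz archive (keys ``level_<name>``)."""
        arrays = {
            f"level_{name}": (l.data if isinstance(l, Tensor) else np.asarray(l))
            for name, l in zip(self.level_names, self.levels)
        }
        np.savez_compressed(path, names=np.array(self.level_names), **arrays)

    @classmethod
    def load(cls, path) -> "FeaturePyramid":
        with np.load(path, allow_pickle=False) as archive:
            names = [str(n) for n in archive["names"]]
            levels = [archive[f"level_{n}"] for n in names]
        return cls(levels=levels, level_names=names)


@dataclass
class BalancedSemanticMap:
    """The balanced mean of all rescaled pyramid levels, at one level's shape."""

    map: object  # ndarray or Tensor, C x H_m x W_m
    source_level_index: int

    @property
    def data(self) -> np.ndarray:
        return self.map.data if isinstance(self.map, Tensor) else np.asarray(self.map)


def _nearest_indices(n_in: int, n_out: int) -> np.ndarray:
    # pixel-centre convention: out pixel i samples in pixel floor((i+0.5)*n_in/n_out)
    idx = np.floor((np.arange(n_out) + 0.5) * n_in / n_out).astype(np.intp)
    return np.clip(idx, 0, n_in - 1)


def _rescale_t(x: Tensor, to_shape: tuple[int, int], mode: str) -> Tensor:
    h_in, w_in = x.shape[-2:]
    h_out, w_out = int(to_shape[0]), int(to_shape[1])
    if h_out <= 0 or w_out <= 0 or h_in == 0 or w_in == 0:
        raise ValueError("zero-sized feature map in rescale")
    if mode not in ("down", "up"):
        raise ValueError(f"mode must be 'down' or 'up', got {mode!r}")
    if (h_out, w_out) == (h_in, w_in):
        return x
    if mode == "down" and (h_out > h_in or w_out > w_in):
        raise ValueError(f"mode='down' cannot enlarge {h_in}x{w_in} -> {h_out}x{w_out}")
    if mode == "up" and (h_out < h_in or w_out < w_in):
        raise ValueError(f"mode='up' cannot shrink {h_in}x{w_in} -> {h_out}x{w_out}")
    if mode == "down" and h_in % h_out == 0 and w_in % w_out == 0:
        kh, kw = h_in // h_out, w_in // w_out
        lead = x.shape[:-2]
        pooled = x.reshape(*lead, h_out, kh, w_out, kw)
        return pooled.amax(axis=(-3, -1))
    # non-integer factors (odd shapes from ceil-halving) and all upscaling:
    # nearest-neighbour interpolation to the exact target shape
    rows = _nearest_indices(h_in, h_out)
    cols = _nearest_indices(w_in, w_out)
    return gather_hw(x, rows, cols)


def rescale_to_level(map_, to_shape: tuple[int, int], mode: str):
    """Rescale a feature map's trailing H x W axes to ``to_shape``.

    ``mode='down'`` uses non-overlapping max pooling when the scale factor is
    an integer (e.g. one pool of kernel 4 for a two-octave jump) and falls
    back to nearest-neighbour sampling otherwise; ``mode='up'`` always uses
    nearest-neighbour interpolation.  Equal shapes are the identity in either
    mode.
    """
    out = _rescale_t(astensor(map_), to_shape, mode)
    return out if isinstance(map_, Tensor) else out.data


def _mode_for(from_hw: tuple[int, int], to_hw: tuple[int, int]) -> str:
    return "down" if from_hw[0] * from_hw[1] >= to_hw[0] * to_hw[1] else "up"


def integrate(pyramid: FeaturePyramid, intermediate_index: int | None = None) -> BalancedSemanticMap:
    """Average all levels, rescaled to the intermediate level, into one map.

    Implements the balanced mean ``C_bar = (1/N) * sum_r C_r`` over levels
    rescaled to a common resolution.  No learned parameters are involved.
    """
    n = pyramid.num_levels
    if intermediate_index is None:
        intermediate_index = n // 2
    if not 0 <= intermediate_index < n:
        raise ValueError(f"intermediate_index {intermediate_index} outside [0, {n})")
    counts = pyramid.channel_counts()
    if len(set(counts)) != 1:
        raise ValueError(f"all levels must share a channel count, got {counts}")
    target_hw = pyramid.spatial_shapes()[intermediate_index]
    total = None
    for lvl in pyramid.levels:
        t = astensor(lvl)
        rescaled = _rescale_t(t, target_hw, _mode_for(t.shape[-2:], target_hw))
        total = rescaled if total is None else total + rescaled
    balanced = total * (1.0 / n)
    if not _is_tensor_like(pyramid.levels):
        balanced = balanced.data
    return BalancedSemanticMap(map=balanced, source_level_index=intermediate_index)


def strengthen(pyramid: FeaturePyramid, refined: BalancedSemanticMap) -> FeaturePyramid:
    """Add the (refined) balanced map, rescaled per level, back onto every level."""
    idx = refined.source_level_index
    ref_t = astensor(refined.map)
    expect_hw = pyramid.spatial_shapes()[idx]
    if tuple(ref_t.shape[-2:]) != tuple(expect_hw):
        raise ValueError(
            f"refined map shape {ref_t.shape[-2:]} does not match level {idx} shape {expect_hw}"
        )
    if ref_t.shape[-3] != pyramid.channel_count:
        raise ValueError("refined map channel count does not match the pyramid")
    out_levels = []
    for lvl in pyramid.levels:
        t = astensor(lvl)
        hw = t.shape[-2:]
        add = _rescale_t(ref_t, hw, _mode_for(ref_t.shape[-2:], hw))
        out_levels.append(t + add)
    if not (_is_tensor_like(pyramid.levels) or isinstance(refined.map, Tensor)):
        out_levels = [t.data for t in out_levels]
    return FeaturePyramid(levels=out_levels, level_names=list(pyramid.level_names))
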