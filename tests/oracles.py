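"""Independent brute-force oracles used by the test suite.

Every function here recomputes a package operation by a different route —
scalar loops, closed forms, or third-party primitives — and must stay
independent of the implementation it checks.
"""

import math

import numpy as np
from skimage.measure import block_reduce


def oracle_resize(level: np.ndarray, to_hw) -> np.ndarray:
    """Resize C x H x W with third-party/naive primitives.

    Integer downscale: skimage block_reduce with max.  Integer upscale:
    np.repeat along both axes.  Otherwise: explicit nearest-neighbour
    pixel-centre sampling with scalar loops.
    """
    c, h, w = level.shape
    th, tw = to_hw
    if (th, tw) == (h, w):
        return level.copy()
    if h % th == 0 and w % tw == 0 and th <= h:
        return block_reduce(level, (1, h // th, w // tw), np.max)
    if th % h == 0 and tw % w == 0 and th >= h:
        return np.repeat(np.repeat(level, th // h, axis=1), tw // w, axis=2)
    out = np.zeros((c, th, tw), dtype=level.dtype)
    for i in range(th):
        for j in range(tw):
            si = min(h - 1, int(math.floor((i + 0.5) * h / th)))
            sj = min(w - 1, int(math.floor((j + 0.5) * w / tw)))
            out[:, i, j] = level[:, si, sj]
    return out


def oracle_integrate(levels, intermediate_index: int) -> np.ndarray:
    """Loop-resize-sum-divide balanced mean."""
    target = levels[intermediate_index].shape[1:]
    total = np.zeros((levels[0].shape[0], *target), dtype=np.float64)
    for lvl in levels:
        total += oracle_resize(lvl.astype(np.float64), target)
    return total / len(levels)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def oracle_channel_gate(f: np.ndarray, w0, b0, w1, b1) -> np.ndarray:
    """Scalar-arithmetic shared-MLP channel gate."""
    c = f.shape[0]
    avg = [float(f[ch].mean()) for ch in range(c)]
    mx = [float(f[ch].max()) for ch in range(c)]

    def mlp(vec):
        hidden = []
        for i in range(w0.shape[0]):
            s = sum(float(w0[i, j]) * vec[j] for j in range(c))
            if b0 is not None:
                s += float(b0[i])
            hidden.append(max(0.0, s))
        out = []
        for i in range(c):
            s = sum(float(w1[i, j]) * hidden[j] for j in range(w0.shape[0]))
            if b1 is not None:
                s += float(b1[i])
            out.append(s)
        return out

    a, m = mlp(avg), mlp(mx)
    return np.array([_sigmoid(a[i] + m[i]) for i in range(c)])


def oracle_spatial_gate(f: np.ndarray, kernel, bias) -> np.ndarray:
    """Scalar-loop 7x7 convolution of the [avg; max] planes, zero padding 3."""
    c, h, w = f.shape
    planes = [f.mean(axis=0), f.max(axis=0)]
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            s = float(bias[0]) if bias is not None else 0.0
            for p in range(2):
                for dy in range(-3, 4):
                    for dx in range(-3, 4):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w:
                            s += float(kernel[0, p, dy + 3, dx + 3]) * float(planes[p][yy, xx])
            out[y, x] = _sigmoid(s)
    return out


def oracle_abfp_refine(f: np.ndarray, cap, sap) -> np.ndarray:
    """Element-wise parallel-additive refinement from the scalar gates."""
    mc = oracle_channel_gate(f, cap.w0, cap.b0, cap.w1, cap.b1)
    ms = oracle_spatial_gate(f, sap.kernel, sap.bias)
    c, h, w = f.shape
    out = np.zeros((c, h, w))
    for ch in range(c):
        for y in range(h):
            for x in range(w):
                v = float(f[ch, y, x])
                out[ch, y, x] = mc[ch] * v + ms[y, x] * v
    return out


def oracle_average_precision(pr_points: np.ndarray) -> float:
    """101-point AP by brute scan: for each grid recall, the maximum
    precision over all PR points with recall >= r."""
    pr_points = np.asarray(pr_points, dtype=np.float64).reshape(-1, 2)
    total = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        best = 0.0
        for rec, prec in pr_points:
            if rec >= r and prec > best:
                best = prec
        total += best
    return total / 101.0


def finite_difference_grad(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    x = x.astype(np.float64)
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        grad[idx] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return grad
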