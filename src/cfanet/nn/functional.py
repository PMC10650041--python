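"""Differentiable numpy kernels used by the network layers.

Convolutions run as im2col + a single BLAS ``sgemm`` (with a cheap fast path
for 1x1 kernels); their backward passes are the exact adjoint GEMMs.  Bilinear
interpolation is expressed as two small interpolation matrices applied along
the spatial axes, so its adjoint is the transposed matrices — this keeps
up/downsampling exactly linear and its gradient exact.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

from .autograd import Tensor

__all__ = [
    "add", "sub", "mul", "div", "concat", "relu", "sigmoid",
    "conv2d", "batch_norm2d", "max_pool2d", "upsample_bilinear",
    "global_avg_pool", "global_max_pool", "channel_mean", "channel_max",
    "sum_tensor", "mean_tensor",
]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(g, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(-g, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(g * a.data, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(g * (out_data > 0))

    return Tensor._make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = expit(x.data)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate_grad(g[tuple(sl)])

    return Tensor._make(out_data, tensors, backward)


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def sum_tensor(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not x.requires_grad:
            return
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x.accumulate_grad(np.broadcast_to(g, x.data.shape).astype(np.float32))

    return Tensor._make(out_data, (x,), backward)


def mean_tensor(x: Tensor) -> Tensor:
    n = x.data.size
    out_data = x.data.mean()

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(np.full(x.data.shape, float(g) / n, dtype=np.float32))

    return Tensor._make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

# Winograd F(2x2, 3x3) kernel transform: U = G w G^T
_WINOGRAD_G = np.array(
    [[1.0, 0.0, 0.0], [0.5, 0.5, 0.5], [0.5, -0.5, 0.5], [0.0, 0.0, 1.0]],
    dtype=np.float32,
)


def _winograd3x3(xp: np.ndarray, weight: np.ndarray, out: np.ndarray | None = None) -> np.ndarray:
    """Valid 3x3 cross-correlation of pre-padded ``xp`` via Winograd F(2x2,3x3).

    Requires even output dims.  The data transforms are expressed as
    full-array shifted adds (cheap, cache-friendly); the 16 per-position
    contractions are plain batched GEMMs with a 2.25x multiply saving over
    direct convolution.
    """
    n, c, hp, wp = xp.shape
    ho, wo = hp - 2, wp - 2
    ta, tb = ho // 2, wo // 2
    cout = weight.shape[0]
    # row transform: R_i = sum_k BT[i,k] * (rows 2a+k), BT rows of F(2,3)
    s = [xp[:, :, k::2, :][:, :, :ta, :] for k in range(4)]  # (N,C,ta,wp) views
    r = (s[0] - s[2], s[1] + s[2], s[2] - s[1], s[1] - s[3])
    u = np.matmul(np.matmul(_WINOGRAD_G, weight), _WINOGRAD_G.T)  # (O,C,4,4)
    t = ta * tb
    m = np.empty((4, 4, n, cout, t), dtype=np.float32)
    for i in range(4):
        ri = r[i]
        col = [ri[:, :, :, k::2][:, :, :, :tb] for k in range(4)]
        v = (col[0] - col[2], col[1] + col[2], col[2] - col[1], col[1] - col[3])
        for j in range(4):
            vj = np.ascontiguousarray(v[j]).reshape(n, c, t)
            np.matmul(u[:, :, i, j], vj, out=m[i, j])
    # inverse transform A^T M A with A^T = [[1,1,1,0],[0,1,-1,-1]]
    p0 = m[0] + m[1] + m[2]
    p1 = m[1] - m[2] - m[3]
    q = (
        p0[0] + p0[1] + p0[2],
        p0[1] - p0[2] - p0[3],
        p1[0] + p1[1] + p1[2],
        p1[1] - p1[2] - p1[3],
    )  # (even,even), (even,odd), (odd,even), (odd,odd) output phases
    if out is None:
        out = np.empty((n, cout, ho, wo), dtype=np.float32)
    out[:, :, 0::2, 0::2] = q[0].reshape(n, cout, ta, tb)
    out[:, :, 0::2, 1::2] = q[1].reshape(n, cout, ta, tb)
    out[:, :, 1::2, 0::2] = q[2].reshape(n, cout, ta, tb)
    out[:, :, 1::2, 1::2] = q[3].reshape(n, cout, ta, tb)
    return out


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    n, c, _, _ = xp.shape
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    if stride > 1:
        win = win[:, :, ::stride, ::stride]
    _, _, ho, wo, _, _ = win.shape
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n * ho * wo, c * kh * kw), ho, wo


def _unpad_adjoint(dxp: np.ndarray, p: int, mode: str) -> np.ndarray:
    """Adjoint of the forward padding: crop (zeros) or fold borders (edge)."""
    if mode == "zeros":
        return dxp[:, :, p:-p, p:-p]
    # edge padding copies border pixels outward, so its adjoint sums the
    # padded frame back into the border pixels
    dxp[:, :, p, :] += dxp[:, :, :p, :].sum(axis=2)
    dxp[:, :, -p - 1, :] += dxp[:, :, -p:, :].sum(axis=2)
    dxp = dxp[:, :, p:-p, :]
    dxp[:, :, :, p] += dxp[:, :, :, :p].sum(axis=3)
    dxp[:, :, :, -p - 1] += dxp[:, :, :, -p:].sum(axis=3)
    return dxp[:, :, :, p:-p]


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Optional[Tensor] = None,
    stride: int = 1,
    padding: int = 0,
    padding_mode: str = "zeros",
) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel/stride/padding."""
    n, c, h, w = x.data.shape
    cout, cin, kh, kw = weight.data.shape
    if cin != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {cin}")
    wmat = weight.data.reshape(cout, cin * kh * kw)

    if kh == 1 and kw == 1 and stride == 1 and padding == 0:
        # fast path: pure channel mixing
        out = np.matmul(wmat, x.data.reshape(n, c, h * w))
        if bias is not None:
            out += bias.data.reshape(1, cout, 1)
        out_data = out.reshape(n, cout, h, w)

        def backward(g):
            gf = g.reshape(n, cout, h * w)
            if weight.requires_grad:
                dw = np.einsum("noq,ncq->oc", gf, x.data.reshape(n, c, h * w), optimize=True)
                weight.accumulate_grad(dw.reshape(weight.data.shape))
            if bias is not None and bias.requires_grad:
                bias.accumulate_grad(gf.sum(axis=(0, 2)))
            if x.requires_grad:
                dx = np.matmul(wmat.T, gf).reshape(n, c, h, w)
                x.accumulate_grad(dx)

        parents = (x, weight) if bias is None else (x, weight, bias)
        return Tensor._make(out_data, parents, backward)

    if padding > 0:
        pads = ((0, 0), (0, 0), (padding, padding), (padding, padding))
        xp = (np.pad(x.data, pads) if padding_mode == "zeros"
              else np.pad(x.data, pads, mode=padding_mode))
    else:
        xp = x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1

    use_taps = stride == 1 and ho * wo >= 1024  # im2col wins on small maps
    use_winograd = use_taps and kh == 3 and kw == 3 and ho % 2 == 0 and wo % 2 == 0
    if use_winograd:
        acc = _winograd3x3(xp, weight.data)
        if bias is not None:
            acc += bias.data.reshape(1, cout, 1, 1)
        out_data = acc
    elif use_taps:
        # Tap decomposition: for each kernel offset (i, j) run one GEMM over
        # full-width row bands of the (padded) input.  The row band
        # xp[:, :, i:i+ho, :] flattens to a valid strided (N, C, ho*wp) view,
        # so no im2col copy is needed; only a narrow shifted-slice add.
        acc = np.zeros((n, cout, ho, wo), dtype=np.float32)
        zbuf = np.empty((n, kw * cout, ho * wp), dtype=np.float32)
        for i in range(kh):
            band = xp[:, :, i:i + ho, :].reshape(n, c, ho * wp)
            # one GEMM covers all kw column offsets: stack them along rows
            wstack = np.ascontiguousarray(
                weight.data[:, :, i, :].transpose(2, 0, 1)
            ).reshape(kw * cout, c)
            np.matmul(wstack, band, out=zbuf)
            z5 = zbuf.reshape(n, kw, cout, ho, wp)
            for j in range(kw):
                acc += z5[:, j, :, :, j:j + wo]
        if bias is not None:
            acc += bias.data.reshape(1, cout, 1, 1)
        out_data = acc
    else:
        cols, ho, wo = _im2col(xp, kh, kw, stride)
        out = cols @ wmat.T
        if bias is not None:
            out += bias.data
        out_data = np.ascontiguousarray(
            out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
        )

    def backward(g):
        g = np.ascontiguousarray(g)
        if weight.requires_grad:
            if use_taps:
                # mirror of the forward tap decomposition: contract g against
                # full-width row bands, realigning g per column offset
                dw = np.empty_like(weight.data)
                gwide = np.zeros((n, cout, ho, wp), dtype=np.float32)
                for j in range(kw):
                    gwide[:, :, :, j:j + wo] = g.reshape(n, cout, ho, wo)
                    gw3 = gwide.reshape(n, cout, ho * wp)
                    for i in range(kh):
                        band = xp[:, :, i:i + ho, :].reshape(n, c, ho * wp)
                        dw[:, :, i, j] = np.matmul(
                            gw3, band.transpose(0, 2, 1)
                        ).sum(axis=0)
                    gwide[:, :, :, j:j + wo] = 0.0
                weight.accumulate_grad(dw)
            else:
                # im2col is recomputed here instead of cached: it trades a
                # memory-bound copy for a large reduction in peak RSS.
                gf = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, cout)
                cols_b, _, _ = _im2col(xp, kh, kw, stride)
                weight.accumulate_grad((gf.T @ cols_b).reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias.accumulate_grad(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if use_winograd:
                gp = np.pad(g, ((0, 0), (0, 0), (2, 2), (2, 2)))
                wflip = np.ascontiguousarray(
                    weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                )
                dxp = _winograd3x3(gp, wflip)
            elif use_taps:
                g3 = g.reshape(n, cout, ho * wo)
                dxp = np.zeros_like(xp)
                zbuf = np.empty((n, kw * c, ho * wo), dtype=np.float32)
                for i in range(kh):
                    wstack = np.ascontiguousarray(
                        weight.data[:, :, i, :].transpose(2, 1, 0)
                    ).reshape(kw * c, cout)
                    np.matmul(wstack, g3, out=zbuf)
                    z5 = zbuf.reshape(n, kw, c, ho, wo)
                    for j in range(kw):
                        dxp[:, :, i:i + ho, j:j + wo] += z5[:, j]
            elif stride == 1:
                # small maps: correlation with the flipped kernel, no dilation
                gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
                gcols, gho, gwo = _im2col(gp, kh, kw, 1)
                wflip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                wfmat = np.ascontiguousarray(wflip).reshape(c, cout * kh * kw)
                dxp_t = (gcols @ wfmat.T).reshape(n, gho, gwo, c).transpose(0, 3, 1, 2)
                dxp = np.ascontiguousarray(dxp_t)
            else:
                # dX as a correlation with the spatially flipped,
                # channel-swapped kernel: one im2col + one GEMM instead of a
                # col2im scatter.
                gd = np.zeros((n, cout, hp - kh + 1, wp - kw + 1), dtype=np.float32)
                gd[:, :, ::stride, ::stride] = g
                gp = np.pad(gd, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
                gcols, gho, gwo = _im2col(gp, kh, kw, 1)
                wflip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                wfmat = np.ascontiguousarray(wflip).reshape(c, cout * kh * kw)
                dxp_t = (gcols @ wfmat.T).reshape(n, gho, gwo, c).transpose(0, 3, 1, 2)
                dxp = np.ascontiguousarray(dxp_t)
            if padding > 0:
                dxp = _unpad_adjoint(dxp, padding, padding_mode)
            x.accumulate_grad(np.ascontiguousarray(dxp))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data, parents, backward)


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

def batch_norm2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    n, c, h, w = x.data.shape
    if training:
        m = n * h * w
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        unbiased = var * (m / max(m - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        m = n * h * w
        mean = running_mean
        var = running_var
    invstd = 1.0 / np.sqrt(var + eps)
    mean_r = mean.reshape(1, c, 1, 1).astype(np.float32)
    invstd_r = invstd.reshape(1, c, 1, 1).astype(np.float32)
    xhat = (x.data - mean_r) * invstd_r
    out_data = xhat * weight.data.reshape(1, c, 1, 1) + bias.data.reshape(1, c, 1, 1)

    def backward(g):
        if weight.requires_grad:
            weight.accumulate_grad((g * xhat).sum(axis=(0, 2, 3)))
        if bias.requires_grad:
            bias.accumulate_grad(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gw = g * weight.data.reshape(1, c, 1, 1)
            if training:
                s1 = gw.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gw * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (invstd_r / m) * (m * gw - s1 - xhat * s2)
            else:
                dx = gw * invstd_r
            x.accumulate_grad(dx.astype(np.float32))

    return Tensor._make(out_data, (x, weight, bias), backward)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    n, c, h, w = x.data.shape
    if padding > 0:
        xp = np.pad(
            x.data,
            ((0, 0), (0, 0), (padding, padding), (padding, padding)),
            constant_values=-np.inf,
        )
    else:
        xp = x.data
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    _, _, ho, wo, _, _ = win.shape
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxp = np.zeros(xp.shape, dtype=np.float32)
        ki, kj = np.divmod(idx, kernel)
        rows = (np.arange(ho)[None, None, :, None] * stride + ki)
        cols = (np.arange(wo)[None, None, None, :] * stride + kj)
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (nn, cc, rows, cols), g)
        if padding > 0:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x.accumulate_grad(dxp)

    return Tensor._make(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(np.broadcast_to(g / (h * w), x.data.shape).astype(np.float32))

    return Tensor._make(out_data, (x,), backward)


def global_max_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1).reshape(n, c, 1, 1)

    def backward(g):
        if not x.requires_grad:
            return
        dx = np.zeros((n, c, h * w), dtype=np.float32)
        np.put_along_axis(dx, idx[..., None], g.reshape(n, c, 1), axis=-1)
        x.accumulate_grad(dx.reshape(n, c, h, w))

    return Tensor._make(out_data, (x,), backward)


def channel_mean(x: Tensor) -> Tensor:
    c = x.data.shape[1]
    out_data = x.data.mean(axis=1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(np.broadcast_to(g / c, x.data.shape).astype(np.float32))

    return Tensor._make(out_data, (x,), backward)


def channel_max(x: Tensor) -> Tensor:
    idx = x.data.argmax(axis=1, keepdims=True)
    out_data = np.take_along_axis(x.data, idx, axis=1)

    def backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            np.put_along_axis(dx, idx, g, axis=1)
            x.accumulate_grad(dx)

    return Tensor._make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# bilinear interpolation
# ---------------------------------------------------------------------------

_interp_cache: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (align_corners=False)."""
    key = (n_in, n_out)
    mat = _interp_cache.get(key)
    if mat is not None:
        return mat
    coords = (np.arange(n_out, dtype=np.float64) + 0.5) * (n_in / n_out) - 0.5
    coords = np.clip(coords, 0.0, n_in - 1.0)
    i0 = np.floor(coords).astype(np.int64)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = (coords - i0).astype(np.float32)
    mat = np.zeros((n_out, n_in), dtype=np.float32)
    rows = np.arange(n_out)
    mat[rows, i0] += 1.0 - frac
    mat[rows, i1] += frac
    _interp_cache[key] = mat
    return mat


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Resize to ``size`` with bilinear interpolation (align_corners=False)."""
    n, c, h, w = x.data.shape
    ho, wo = size
    if (ho, wo) == (h, w):
        # identity: still record a node so the tape stays uniform
        def backward_id(g):
            if x.requires_grad:
                x.accumulate_grad(g)

        return Tensor._make(x.data, (x,), backward_id)
    wr = _interp_matrix(h, ho)
    wc = _interp_matrix(w, wo)
    flat = x.data.reshape(n * c, h, w)
    out_data = np.matmul(np.matmul(wr, flat), wc.T).reshape(n, c, ho, wo)

    def backward(g):
        if x.requires_grad:
            gf = g.reshape(n * c, ho, wo)
            dx = np.matmul(np.matmul(wr.T, gf), wc).reshape(n, c, h, w)
            x.accumulate_grad(dx.astype(np.float32))

    return Tensor._make(out_data, (x,), backward)
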