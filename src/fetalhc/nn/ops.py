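"""Differentiable operations (NCHW layout).

Convolutions use im2col + BLAS matmul; the input gradient is reassembled
with k*k strided slice-adds rather than a per-element scatter. Padding is
given as ``(top, bottom, left, right)`` so even kernels can keep "same"
spatial size the way TF/Keras pad (extra row/col at bottom/right).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, make

__all__ = [
    "add", "relu", "sigmoid", "conv2d", "conv_transpose2x2", "upsample2x",
    "subsample2", "maxpool2d", "batchnorm2d", "linear", "flatten",
    "concat_rows", "index_rows", "roi_align",
    "softmax_cross_entropy", "bce_with_logits", "smooth_l1", "field_rmse_loss",
]


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data
    return make(out, [(a, lambda g: g), (b, lambda g: g)])


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return make(x.data * mask, [(x, lambda g: g * mask)])


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return make(s, [(x, lambda g: g * s * (1.0 - s))])


# ---------------------------------------------------------------------------
# convolution


def _pad4(x: np.ndarray, pad):
    pt, pb, pl, pr = pad
    if pt or pb or pl or pr:
        return np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    return x


def _im2col(xp: np.ndarray, k: int, stride: int):
    n, c, hp, wp = xp.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # n, c, ho, wo, k, k
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * k * k)
    return cols, ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           pad=(0, 0, 0, 0)) -> Tensor:
    """2-D correlation. ``w``: (Cout, Cin, k, k); ``pad``: (t, b, l, r)."""
    if isinstance(pad, int):
        pad = (pad, pad, pad, pad)
    n, c, h, wd = x.data.shape
    cout, cin, k, _ = w.data.shape
    if k == 1 and pad == (0, 0, 0, 0):
        return _conv1x1(x, w, b, stride)
    xp = _pad4(x.data, pad)
    cols, ho, wo = _im2col(xp, k, stride)
    w2 = w.data.reshape(cout, cin * k * k)
    out = cols @ w2.T
    if b is not None:
        out += b.data
    out = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)

    hp, wp = xp.shape[2], xp.shape[3]

    def grad_x(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        gcols = g2 @ w2  # (n*ho*wo, cin*k*k)
        gg = gcols.reshape(n, ho, wo, cin, k, k)
        dxp = np.zeros((n, cin, hp, wp), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + stride * ho:stride,
                    j:j + stride * wo:stride] += gg[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        pt, pb, pl, pr = pad
        return dxp[:, :, pt:pt + h, pl:pl + wd]

    def grad_w(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        return (g2.T @ cols).reshape(cout, cin, k, k)

    parents = [(x, grad_x), (w, grad_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return make(out, parents)


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None, stride: int) -> Tensor:
    """Pointwise convolution as a single matmul."""
    xs = x.data if stride == 1 else np.ascontiguousarray(
        x.data[:, :, ::stride, ::stride])
    n, c, h, wd = xs.shape
    cout = w.data.shape[0]
    w2 = w.data.reshape(cout, c)
    flat = xs.reshape(n, c, h * wd)
    out = np.matmul(w2[None], flat)  # (n, cout, h*wd)
    if b is not None:
        out += b.data[None, :, None]
    out = out.reshape(n, cout, h, wd)
    in_shape = x.data.shape

    def grad_x(g):
        gf = g.reshape(n, cout, h * wd)
        dxs = np.matmul(w2.T[None], gf).reshape(n, c, h, wd)
        if stride == 1:
            return dxs
        dx = np.zeros(in_shape, dtype=np.float32)
        dx[:, :, ::stride, ::stride] = dxs
        return dx

    def grad_w(g):
        gf = g.reshape(n, cout, h * wd)
        return np.matmul(gf, flat.transpose(0, 2, 1)).sum(axis=0).reshape(
            cout, c, 1, 1)

    parents = [(x, grad_x), (w, grad_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return make(out, parents)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Transposed conv, kernel 2, stride 2 (blocks do not overlap).

    ``w``: (Cin, Cout, 2, 2); output is exactly 2x the spatial size.
    """
    n, c, h, wd = x.data.shape
    cout = w.data.shape[1]
    t = np.tensordot(x.data, w.data, axes=([1], [0]))  # n,h,w,cout,2,2
    out = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, cout, 2 * h, 2 * wd)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def grad_x(g):
        gg = g.reshape(n, cout, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)
        return np.tensordot(gg, w.data, axes=([3, 4, 5], [1, 2, 3])).transpose(0, 3, 1, 2)

    def grad_w(g):
        gg = g.reshape(n, cout, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)
        return np.tensordot(x.data, gg, axes=([0, 2, 3], [0, 1, 2]))

    parents = [(x, grad_x), (w, grad_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return make(out, parents)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.data.shape

    def grad_x(g):
        return g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))

    return make(out, [(x, grad_x)])


def subsample2(x: Tensor) -> Tensor:
    """Stride-2 subsampling (1x1 max-pool with stride 2)."""
    out = np.ascontiguousarray(x.data[:, :, ::2, ::2])
    shape = x.data.shape

    def grad_x(g):
        dx = np.zeros(shape, dtype=np.float32)
        dx[:, :, ::2, ::2] = g
        return dx

    return make(out, [(x, grad_x)])


def maxpool2d(x: Tensor, k: int = 3, stride: int = 2, pad: int = 1) -> Tensor:
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, k * k)
    idx = flat.argmax(axis=4)
    out = np.take_along_axis(flat, idx[..., None], axis=4)[..., 0]
    hp, wp = xp.shape[2], xp.shape[3]

    def grad_x(g):
        dxp = np.zeros((n, c, hp * wp), dtype=np.float32)
        iy = idx // k
        ix = idx % k
        oy = np.arange(ho)[None, None, :, None] * stride
        ox = np.arange(wo)[None, None, None, :] * stride
        lin = ((oy + iy) * wp + (ox + ix)).reshape(n, c, -1)
        nn = np.arange(n)[:, None, None]
        cc = np.arange(c)[None, :, None]
        np.add.at(dxp, (nn, cc, lin), g.reshape(n, c, -1))
        return dxp.reshape(n, c, hp, wp)[:, :, pad:pad + h, pad:pad + w]

    return make(out.astype(np.float32), [(x, grad_x)])


# ---------------------------------------------------------------------------
# normalization / dense


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
                running_var, momentum: float, eps: float,
                training: bool) -> Tensor:
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def grad_x(g):
        gi = gamma.data * inv
        if not training:
            return g * gi[None, :, None, None]
        gm = g.mean(axis=(0, 2, 3))
        gxm = (g * xhat).sum(axis=(0, 2, 3)) / m
        return gi[None, :, None, None] * (
            g - gm[None, :, None, None] - xhat * gxm[None, :, None, None])

    def grad_gamma(g):
        return (g * xhat).sum(axis=(0, 2, 3))

    def grad_beta(g):
        return g.sum(axis=(0, 2, 3))

    return make(out.astype(np.float32),
                [(x, grad_x), (gamma, grad_gamma), (beta, grad_beta)])


def linear(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """``x``: (N, D), ``w``: (Out, D)."""
    out = x.data @ w.data.T
    if b is not None:
        out = out + b.data
    parents = [(x, lambda g: g @ w.data), (w, lambda g: g.T @ x.data)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=0)))
    return make(out, parents)


def flatten(x: Tensor) -> Tensor:
    n = x.data.shape[0]
    shape = x.data.shape
    out = np.ascontiguousarray(x.data).reshape(n, -1)
    return make(out, [(x, lambda g: g.reshape(shape))])


def concat_rows(tensors) -> Tensor:
    """Concatenate along axis 0."""
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=0)
    parents = []
    off = 0
    for t in tensors:
        n = t.data.shape[0]
        start = off

        def fn(g, s=start, e=off + n):
            return g[s:e]

        parents.append((t, fn))
        off += n
    return make(out, parents)


def index_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx)
    out = x.data[idx]
    shape = x.data.shape

    def grad_x(g):
        dx = np.zeros(shape, dtype=np.float32)
        np.add.at(dx, idx, g)
        return dx

    return make(out, [(x, grad_x)])


# ---------------------------------------------------------------------------
# ROI align


def roi_align(feat: Tensor, boxes: np.ndarray, out_size: int,
              spatial_scale: float, sampling: int = 2) -> Tensor:
    """Quantization-free bilinear pooling of box regions to d x d.

    ``feat``: (1, C, H, W); ``boxes``: (n, 4) as [x1, y1, x2, y2] in input
    image coordinates. Each output bin averages ``sampling**2`` bilinear
    samples placed on a regular sub-grid inside the bin.
    """
    assert feat.data.shape[0] == 1
    _, c, h, w = feat.data.shape
    boxes = np.asarray(boxes, dtype=np.float64) * spatial_scale
    n = boxes.shape[0]
    d, s = out_size, sampling
    if n == 0:
        return Tensor(np.zeros((0, c, d, d), dtype=np.float32))

    bw = np.maximum(boxes[:, 2] - boxes[:, 0], 1e-6)
    bh = np.maximum(boxes[:, 3] - boxes[:, 1], 1e-6)
    # sample coordinates: (n, d*s) along each axis
    steps = (np.arange(d * s) + 0.5) / s  # in bin units of 1/s
    ys = boxes[:, 1, None] + bh[:, None] * steps[None, :] / d
    xs = boxes[:, 0, None] + bw[:, None] * steps[None, :] / d
    # pixel-center convention: continuous coord p samples pixels floor(p-0.5)..
    ys = np.clip(ys - 0.5, 0.0, h - 1.0)
    xs = np.clip(xs - 0.5, 0.0, w - 1.0)
    y0 = np.floor(ys).astype(np.int64)
    x0 = np.floor(xs).astype(np.int64)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    ly = (ys - y0).astype(np.float32)
    lx = (xs - x0).astype(np.float32)

    f = feat.data[0].reshape(c, h * w)
    yy0 = y0[:, :, None]
    yy1 = y1[:, :, None]
    xx0 = x0[:, None, :]
    xx1 = x1[:, None, :]
    i00 = (yy0 * w + xx0).reshape(n, -1)
    i01 = (yy0 * w + xx1).reshape(n, -1)
    i10 = (yy1 * w + xx0).reshape(n, -1)
    i11 = (yy1 * w + xx1).reshape(n, -1)
    wy = ly[:, :, None]
    wx = lx[:, None, :]
    w00 = ((1 - wy) * (1 - wx)).reshape(n, -1)
    w01 = ((1 - wy) * wx).reshape(n, -1)
    w10 = (wy * (1 - wx)).reshape(n, -1)
    w11 = (wy * wx).reshape(n, -1)

    vals = (f[:, i00] * w00 + f[:, i01] * w01 +
            f[:, i10] * w10 + f[:, i11] * w11)  # (c, n, (d*s)^2)
    vals = vals.reshape(c, n, d, s, d, s).mean(axis=(3, 5))
    out = np.ascontiguousarray(vals.transpose(1, 0, 2, 3)).astype(np.float32)

    def grad_feat(g):
        # distribute bin gradients to the 4 neighbours of each sample via a
        # sparse scatter matrix shared across channels
        from scipy import sparse
        gb = (g.transpose(1, 0, 2, 3) / (s * s)).astype(np.float32)
        gs = np.repeat(np.repeat(gb, s, axis=2), s, axis=3).reshape(c, -1)
        npts = gs.shape[1]
        rows = np.tile(np.arange(npts, dtype=np.int64), 4)
        cols = np.concatenate([ii.reshape(-1) for ii in (i00, i01, i10, i11)])
        wv = np.concatenate([ww.reshape(-1).astype(np.float32)
                             for ww in (w00, w01, w10, w11)])
        scat = sparse.csr_matrix((wv, (rows, cols)), shape=(npts, h * w))
        df = scat.T.dot(gs.T).T  # (c, h*w)
        return np.ascontiguousarray(df, dtype=np.float32).reshape(1, c, h, w)

    return make(out, [(feat, grad_feat)])


# ---------------------------------------------------------------------------
# losses (scalar outputs)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = labels.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-12)).mean()

    def grad(g):
        d = p.copy()
        d[np.arange(n), labels] -= 1.0
        return (g * d / n).astype(np.float32)

    return make(np.float32(loss), [(logits, grad)])


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    from scipy.special import expit
    t = np.asarray(targets, dtype=np.float32)
    z = logits.data
    loss = (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))).mean()
    s = expit(z)
    n = z.size

    def grad(g):
        return (g * (s - t) / n).astype(np.float32)

    return make(np.float32(loss), [(logits, grad)])


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0) -> Tensor:
    t = np.asarray(target, dtype=np.float32)
    diff = pred.data - t
    ad = np.abs(diff)
    per = np.where(ad < beta, 0.5 * diff ** 2 / beta, ad - 0.5 * beta)
    loss = per.mean() if per.size else np.float32(0.0)
    n = max(per.size, 1)

    def grad(g):
        d = np.where(ad < beta, diff / beta, np.sign(diff))
        return (g * d / n).astype(np.float32)

    return make(np.float32(loss), [(pred, grad)])


def field_rmse_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-8) -> Tensor:
    """Per-ROI RMSE between field patches, averaged over ROIs.

    ``pred``, ``target``: (n, 1, S, S).
    """
    t = np.asarray(target, dtype=np.float32)
    if pred.data.shape != t.shape:
        raise ValueError(f"shape mismatch {pred.data.shape} vs {t.shape}")
    n = t.shape[0]
    if n == 0:
        return Tensor(np.float32(0.0))
    diff = pred.data - t
    mse = (diff ** 2).mean(axis=(1, 2, 3))
    rmse = np.sqrt(mse + eps)
    loss = rmse.mean()
    m = t[0].size

    def grad(g):
        scale = (g / (n * m)) / rmse
        return (diff * scale[:, None, None, None]).astype(np.float32)

    return make(np.float32(loss), [(pred, grad)])
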