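"""Numba kernels for patch extraction and the attention block's hot loops.

Dense 3x3/1x1 convolutions go through im2col + BLAS (see ``layers.py``);
the stride-1 sliding pooling and the depthwise 7x7 location convolution
replicate data 9x/49x under im2col, so they get direct loops instead.

All kernels are channels-last (N, H, W, C) float32 with inner loops on the
contiguous channel axis, and handle their padding implicitly (zero padding
for convolutions/im2col, edge replication for pooling) so no padded
temporaries are materialised.  Location-convolution weights arrive as
per-channel vectors (kh, kw, 2, C); a parameter set shared across channels
is broadcast to that shape by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _im2col_fill(x, cols, k, pad):
    # x: (N, H, W, C) -> cols (N*H*W, k*k*C) in (k, k, C) order, zero-padded
    N, H, W, C = x.shape
    for n in range(N):
        for y in range(H):
            rowbase = (n * H + y) * W
            for xx in range(W):  # row-major writes: each cols row is contiguous
                dst = cols[rowbase + xx]
                col0 = 0
                for u in range(k):
                    ys = y + u - pad
                    for v in range(k):
                        xs = xx + v - pad
                        if ys < 0 or ys >= H or xs < 0 or xs >= W:
                            for c in range(C):
                                dst[col0 + c] = 0.0
                        else:
                            src = x[n, ys, xs]
                            for c in range(C):
                                dst[col0 + c] = src[c]
                        col0 += C


def im2col(x: np.ndarray, k: int, pad: int):
    """(N, H, W, C) -> (N*H*W, k*k*C) zero-padded patch matrix."""
    x = np.ascontiguousarray(x, dtype=np.float32)
    n, h, w, c = x.shape
    cols = np.empty((n * h * w, k * k * c), dtype=np.float32)
    _im2col_fill(x, cols, k, pad)
    return cols, (n, h, w)


@njit(cache=True)
def _pool_fwd(x, k, avg, mx, idx):
    # edge-replicate stride-1 pooling; idx stores the winning offset u*k+v
    N, H, W, C = x.shape
    p = k // 2
    inv = np.float32(1.0 / (k * k))
    for n in range(N):
        for y in range(H):
            first = True
            for u in range(k):
                ys = min(max(y + u - p, 0), H - 1)
                src = x[n, ys]
                for v in range(k):
                    j = u * k + v
                    if first:
                        for xx in range(W):
                            xs = min(max(xx + v - p, 0), W - 1)
                            for c in range(C):
                                val = src[xs, c]
                                avg[n, y, xx, c] = val
                                mx[n, y, xx, c] = val
                                idx[n, y, xx, c] = 0
                        first = False
                    else:
                        for xx in range(W):
                            xs = min(max(xx + v - p, 0), W - 1)
                            for c in range(C):
                                val = src[xs, c]
                                avg[n, y, xx, c] += val
                                if val > mx[n, y, xx, c]:
                                    mx[n, y, xx, c] = val
                                    idx[n, y, xx, c] = j
            for xx in range(W):
                for c in range(C):
                    avg[n, y, xx, c] *= inv


@njit(cache=True)
def _pool_bwd(g_avg, g_max, idx, k, dx):
    # clamped scatter reproduces the replicate-padding adjoint directly
    N, H, W, C = g_avg.shape
    p = k // 2
    inv = np.float32(1.0 / (k * k))
    for n in range(N):
        for y in range(H):
            for u in range(k):
                ys = min(max(y + u - p, 0), H - 1)
                dst = dx[n, ys]
                for v in range(k):
                    for xx in range(W):
                        xs = min(max(xx + v - p, 0), W - 1)
                        for c in range(C):
                            dst[xs, c] += g_avg[n, y, xx, c] * inv
            for xx in range(W):
                for c in range(C):
                    j = idx[n, y, xx, c]
                    u = j // k
                    v = j - u * k
                    ys = min(max(y + u - p, 0), H - 1)
                    xs = min(max(xx + v - p, 0), W - 1)
                    dx[n, ys, xs, c] += g_max[n, y, xx, c]


@njit(cache=True)
def _conv_pair_fwd(a, m, w, b, out):
    # zero same-padding handled by loop bounds; w: (k, k, 2, C), b: (C,)
    N, H, W, C = out.shape
    k = w.shape[0]
    p = k // 2
    for n in range(N):
        for y in range(H):
            for xx in range(W):
                for c in range(C):
                    out[n, y, xx, c] = b[c]
            for u in range(k):
                ys = y + u - p
                if ys < 0 or ys >= H:
                    continue
                arow = a[n, ys]
                mrow = m[n, ys]
                for v in range(k):
                    wa = w[u, v, 0]
                    wm = w[u, v, 1]
                    xlo = max(0, p - v)
                    xhi = min(W, W + p - v)
                    for xx in range(xlo, xhi):
                        xs = xx + v - p
                        for c in range(C):
                            out[n, y, xx, c] += (wa[c] * arow[xs, c]
                                                 + wm[c] * mrow[xs, c])


@njit(cache=True)
def _conv_pair_bwd(g, wflip, a, m, d_avg, d_max, dw):
    # fused backward-data + weight-grad: one sweep over (n, y), the small
    # (k, k, 2, C) accumulator stays cache-resident
    N, H, W, C = d_avg.shape
    k = wflip.shape[0]
    p = k // 2
    for n in range(N):
        for y in range(H):
            for u in range(k):
                ys = y + u - p
                if ys < 0 or ys >= H:
                    continue
                grow = g[n, ys]
                arow = a[n, ys]
                mrow = m[n, ys]
                gyrow = g[n, y]
                for v in range(k):
                    wa = wflip[u, v, 0]
                    wm = wflip[u, v, 1]
                    xlo = max(0, p - v)
                    xhi = min(W, W + p - v)
                    for xx in range(xlo, xhi):
                        xs = xx + v - p
                        for c in range(C):
                            gg = grow[xs, c]
                            d_avg[n, y, xx, c] += wa[c] * gg
                            d_max[n, y, xx, c] += wm[c] * gg
    # g[n, y, xx+v-p] * plane[n, y+u-p, xx] accumulates tap (u, k-1-v)
                    vf = k - 1 - v
                    for xx in range(xlo, xhi):
                        xs = xx + v - p
                        for c in range(C):
                            gg = gyrow[xs, c]
                            dw[u, vf, 0, c] += gg * arow[xx, c]
                            dw[u, vf, 1, c] += gg * mrow[xx, c]


def sliding_pool_pair(x: np.ndarray, k: int):
    """Stride-1 avg/max pooling with edge-replicate padding, same spatial size.

    ``x`` is (N, H, W, C) float32; returns (avg, max, argmax_index), the
    index encoding the winning window offset ``u * k + v`` for the backward
    pass.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError(f"pool kernel must be odd and positive, got {k}")
    x = np.ascontiguousarray(x, dtype=np.float32)
    avg = np.empty_like(x)
    mx = np.empty_like(x)
    idx = np.empty(x.shape, dtype=np.uint8)
    _pool_fwd(x, k, avg, mx, idx)
    return avg, mx, idx


def sliding_pool_pair_bwd(g_avg: np.ndarray, g_max: np.ndarray,
                          idx: np.ndarray, k: int) -> np.ndarray:
    """Backward of :func:`sliding_pool_pair` w.r.t. its input."""
    dx = np.zeros_like(g_avg)
    _pool_bwd(np.ascontiguousarray(g_avg, dtype=np.float32),
              np.ascontiguousarray(g_max, dtype=np.float32), idx, k, dx)
    return dx


def conv_pair(avg: np.ndarray, mx: np.ndarray, wvec: np.ndarray,
              bvec: np.ndarray) -> np.ndarray:
    """Same-padded correlation of the (avg, max) pair with per-channel kernels.

    ``wvec`` is (k, k, 2, C) and ``bvec`` (C,); sharing across channels is a
    broadcast of one (k, k, 2) kernel.
    """
    out = np.empty_like(avg)
    _conv_pair_fwd(avg, mx, np.ascontiguousarray(wvec, dtype=np.float32),
                   np.ascontiguousarray(bvec, dtype=np.float32), out)
    return out


def conv_pair_bwd(avg: np.ndarray, mx: np.ndarray, wvec: np.ndarray,
                  g: np.ndarray):
    """Gradients of :func:`conv_pair`: (d_avg, d_max, dw (k,k,2,C), db (C,))."""
    g = np.ascontiguousarray(g, dtype=np.float32)
    wflip = np.ascontiguousarray(wvec[::-1, ::-1], dtype=np.float32)
    d_avg = np.zeros_like(avg)
    d_max = np.zeros_like(mx)
    dw = np.zeros(wvec.shape, dtype=np.float32)
    _conv_pair_bwd(g, wflip, avg, mx, d_avg, d_max, dw)
    return d_avg, d_max, dw, g.sum(axis=(0, 1, 2))
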