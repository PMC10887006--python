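"""Numba-compiled inner loops for the 3x3 convolutions.

The dense blocks spend almost all their time in stride-1 'same' 3x3
convolutions at full slice resolution; explicit fused loops avoid the large
temporaries a pure-numpy formulation needs.  Results are bit-for-bit
deterministic (fixed loop order, no threading).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def conv3x3_forward(x, w):
    """x (N,C,H,W), w (O,C,3,3) -> out (N,O,H,W), zero-padded borders."""
    n, c, h, wd = x.shape
    o = w.shape[0]
    out = np.zeros((n, o, h, wd), dtype=x.dtype)
    for nn in range(n):
        for oo in range(o):
            for cc in range(c):
                for ki in range(3):
                    di = ki - 1
                    a0 = -di if di < 0 else 0
                    a1 = h - di if di > 0 else h
                    for kj in range(3):
                        dj = kj - 1
                        b0 = -dj if dj < 0 else 0
                        b1 = wd - dj if dj > 0 else wd
                        wv = w[oo, cc, ki, kj]
                        for i in range(a0, a1):
                            for j in range(b0, b1):
                                out[nn, oo, i, j] += wv * x[nn, cc, i + di, j + dj]
    return out


@njit(cache=True, fastmath=True)
def conv3x3_backward_x(g, w):
    """Gradient wrt the input: g (N,O,H,W), w (O,C,3,3) -> (N,C,H,W)."""
    n, o, h, wd = g.shape
    c = w.shape[1]
    dx = np.zeros((n, c, h, wd), dtype=g.dtype)
    for nn in range(n):
        for cc in range(c):
            for oo in range(o):
                for ki in range(3):
                    di = ki - 1
                    a0 = -di if di < 0 else 0
                    a1 = h - di if di > 0 else h
                    for kj in range(3):
                        dj = kj - 1
                        b0 = -dj if dj < 0 else 0
                        b1 = wd - dj if dj > 0 else wd
                        wv = w[oo, cc, ki, kj]
                        for i in range(a0, a1):
                            for j in range(b0, b1):
                                dx[nn, cc, i + di, j + dj] += wv * g[nn, oo, i, j]
    return dx


@njit(cache=True, fastmath=True)
def conv3x3_backward_w(g, x, c):
    """Gradient wrt the kernel: g (N,O,H,W), x (N,C,H,W) -> (O,C,3,3)."""
    n, o, h, wd = g.shape
    dw = np.zeros((o, c, 3, 3), dtype=g.dtype)
    for nn in range(n):
        for oo in range(o):
            for cc in range(c):
                for ki in range(3):
                    di = ki - 1
                    a0 = -di if di < 0 else 0
                    a1 = h - di if di > 0 else h
                    for kj in range(3):
                        dj = kj - 1
                        b0 = -dj if dj < 0 else 0
                        b1 = wd - dj if dj > 0 else wd
                        acc = 0.0
                        for i in range(a0, a1):
                            for j in range(b0, b1):
                                acc += g[nn, oo, i, j] * x[nn, cc, i + di, j + dj]
                        dw[oo, cc, ki, kj] += acc
    return dw


@njit(cache=True, fastmath=True)
def bn_forward(x, gamma, beta, eps):
    """Single-pass-per-stage batch-norm statistics and output.

    Returns (out, mu, inv) with float64 accumulation of the moments."""
    n, c, h, w = x.shape
    m = n * h * w
    mu = np.empty(c, dtype=x.dtype)
    inv = np.empty(c, dtype=x.dtype)
    out = np.empty_like(x)
    for cc in range(c):
        s = 0.0
        s2 = 0.0
        for nn in range(n):
            for i in range(h):
                for j in range(w):
                    v = x[nn, cc, i, j]
                    s += v
                    s2 += v * v
        mu_c = s / m
        var_c = s2 / m - mu_c * mu_c
        if var_c < 0.0:
            var_c = 0.0
        mu[cc] = mu_c
        inv[cc] = 1.0 / np.sqrt(var_c + eps)
        a = gamma[cc] * inv[cc]
        b = beta[cc] - mu_c * a
        for nn in range(n):
            for i in range(h):
                for j in range(w):
                    out[nn, cc, i, j] = a * x[nn, cc, i, j] + b
    return out, mu, inv


@njit(cache=True, fastmath=True)
def bn_backward(x, mu, inv, gamma, g):
    """Training-mode batch-norm input/parameter gradients."""
    n, c, h, w = x.shape
    m = n * h * w
    gx = np.empty_like(x)
    ggamma = np.empty(c, dtype=x.dtype)
    gbeta = np.empty(c, dtype=x.dtype)
    for cc in range(c):
        t1 = 0.0
        t2 = 0.0
        for nn in range(n):
            for i in range(h):
                for j in range(w):
                    gv = g[nn, cc, i, j]
                    t1 += gv
                    t2 += gv * (x[nn, cc, i, j] - mu[cc]) * inv[cc]
        ggamma[cc] = t2
        gbeta[cc] = t1
        k1 = t1 / m
        k2 = t2 / m
        a = gamma[cc] * inv[cc]
        for nn in range(n):
            for i in range(h):
                for j in range(w):
                    xhat = (x[nn, cc, i, j] - mu[cc]) * inv[cc]
                    gx[nn, cc, i, j] = a * (g[nn, cc, i, j] - k1 - xhat * k2)
    return gx, ggamma, gbeta


@njit(cache=True, fastmath=True)
def bn_stats(buf, c_in, eps):
    """Batch mean and inverse SD over channels [0, c_in) of (N, C, H, W)."""
    n, _, h, w = buf.shape
    m = n * h * w
    mu = np.empty(c_in, dtype=buf.dtype)
    inv = np.empty(c_in, dtype=buf.dtype)
    for cc in range(c_in):
        s = 0.0
        s2 = 0.0
        for nn in range(n):
            for i in range(h):
                for j in range(w):
                    v = buf[nn, cc, i, j]
                    s += v
                    s2 += v * v
        mu_c = s / m
        var_c = s2 / m - mu_c * mu_c
        if var_c < 0.0:
            var_c = 0.0
        mu[cc] = mu_c
        inv[cc] = 1.0 / np.sqrt(var_c + eps)
    return mu, inv


@njit(cache=True, fastmath=True)
def dense_layer_fwd(buf, c_in, gamma, beta, w, bias, mu, inv):
    """One dense layer: BN -> ReLU -> 3x3 conv, writing the conv output into
    channels [c_in, c_in + growth) of the shared block buffer in place."""
    n, _, h, wd = buf.shape
    o = w.shape[0]
    act = np.empty((c_in, h, wd), dtype=buf.dtype)
    for nn in range(n):
        for cc in range(c_in):
            a = gamma[cc] * inv[cc]
            b2 = beta[cc] - mu[cc] * a
            for i in range(h):
                for j in range(wd):
                    v = a * buf[nn, cc, i, j] + b2
                    act[cc, i, j] = v if v > 0.0 else 0.0
        for oo in range(o):
            co = c_in + oo
            for i in range(h):
                for j in range(wd):
                    buf[nn, co, i, j] = bias[oo]
            for cc in range(c_in):
                for ki in range(3):
                    di = ki - 1
                    a0 = -di if di < 0 else 0
                    a1 = h - di if di > 0 else h
                    for kj in range(3):
                        dj = kj - 1
                        b0 = -dj if dj < 0 else 0
                        b1 = wd - dj if dj > 0 else wd
                        wv = w[oo, cc, ki, kj]
                        for i in range(a0, a1):
                            for j in range(b0, b1):
                                buf[nn, co, i, j] += wv * act[cc, i + di, j + dj]


@njit(cache=True, fastmath=True)
def dense_layer_bwd(buf, dbuf, c_in, gamma, beta, w, mu, inv, training):
    """Backward of :func:`dense_layer_fwd`.

    Reads the upstream gradient from dbuf[:, c_in:c_in+growth), accumulates
    the input gradient into dbuf[:, :c_in) and returns the parameter
    gradients (gw, gbias, ggamma, gbeta)."""
    n, _, h, wd = buf.shape
    o = w.shape[0]
    gw = np.zeros_like(w)
    gbias = np.zeros(o, dtype=buf.dtype)
    dpre = np.empty((n, c_in, h, wd), dtype=buf.dtype)
    t1 = np.zeros(c_in, dtype=np.float64)
    t2 = np.zeros(c_in, dtype=np.float64)
    act = np.empty((c_in, h, wd), dtype=buf.dtype)
    plane = np.empty((h, wd), dtype=buf.dtype)
    for nn in range(n):
        for cc in range(c_in):
            a = gamma[cc] * inv[cc]
            b2 = beta[cc] - mu[cc] * a
            for i in range(h):
                for j in range(wd):
                    v = a * buf[nn, cc, i, j] + b2
                    act[cc, i, j] = v if v > 0.0 else 0.0
        for oo in range(o):
            co = c_in + oo
            s = 0.0
            for i in range(h):
                for j in range(wd):
                    s += dbuf[nn, co, i, j]
            gbias[oo] += s
            for cc in range(c_in):
                for ki in range(3):
                    di = ki - 1
                    a0 = -di if di < 0 else 0
                    a1 = h - di if di > 0 else h
                    for kj in range(3):
                        dj = kj - 1
                        b0 = -dj if dj < 0 else 0
                        b1 = wd - dj if dj > 0 else wd
                        wv = w[oo, cc, ki, kj]
                        acc = 0.0
                        for i in range(a0, a1):
                            for j in range(b0, b1):
                                acc += dbuf[nn, co, i, j] * act[cc, i + di, j + dj]
                        gw[oo, cc, ki, kj] += acc
        for cc in range(c_in):
            for i in range(h):
                for j in range(wd):
                    plane[i, j] = 0.0
            for oo in range(o):
                co = c_in + oo
                for ki in range(3):
                    di = ki - 1
                    a0 = -di if di < 0 else 0
                    a1 = h - di if di > 0 else h
                    for kj in range(3):
                        dj = kj - 1
                        b0 = -dj if dj < 0 else 0
                        b1 = wd - dj if dj > 0 else wd
                        wv = w[oo, cc, ki, kj]
                        for i in range(a0, a1):
                            for j in range(b0, b1):
                                plane[i + di, j + dj] += wv * dbuf[nn, co, i, j]
            for i in range(h):
                for j in range(wd):
                    gv = plane[i, j] if act[cc, i, j] > 0.0 else 0.0
                    dpre[nn, cc, i, j] = gv
                    t1[cc] += gv
                    t2[cc] += gv * (buf[nn, cc, i, j] - mu[cc]) * inv[cc]
    m = n * h * wd
    ggamma = np.empty(c_in, dtype=buf.dtype)
    gbeta = np.empty(c_in, dtype=buf.dtype)
    for cc in range(c_in):
        ggamma[cc] = t2[cc]
        gbeta[cc] = t1[cc]
    for nn in range(n):
        for cc in range(c_in):
            a = gamma[cc] * inv[cc]
            if training:
                k1 = t1[cc] / m
                k2 = t2[cc] / m
                for i in range(h):
                    for j in range(wd):
                        xhat = (buf[nn, cc, i, j] - mu[cc]) * inv[cc]
                        dbuf[nn, cc, i, j] += a * (dpre[nn, cc, i, j] - k1 - xhat * k2)
            else:
                for i in range(h):
                    for j in range(wd):
                        dbuf[nn, cc, i, j] += a * dpre[nn, cc, i, j]
    return gw, gbias, ggamma, gbeta
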