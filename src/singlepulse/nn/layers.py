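"""Numpy building blocks for the map-to-map convolutional network.

All activations are float32 in channel-major layout (C, B, H, W): with the
channel axis leading, the im2col patch matrix, the conv matmul result and
the incoming gradients all share one memory order, so convolution reduces
to one slab copy per kernel offset plus a single BLAS matmul, with no
transposes anywhere on the hot path.  This matters: training runs
single-threaded on memory-bandwidth-limited hardware, and the naive
sliding-window-view transpose is an order of magnitude slower.

Convolutions are stride-1, zero-padded 'same'.  The input gradient is the
convolution of the output gradient with the 180-degree-rotated kernels
(channels transposed), which reuses the same machinery.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft

__all__ = [
    "conv2d_forward", "conv2d_backward", "relu_forward", "relu_backward",
    "dropout_forward", "dropout_backward", "avgpool2_forward",
    "avgpool2_backward", "upsample2_forward", "upsample2_backward",
]


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(C, B, H, W) -> (kh*kw*C, B*H*W) patch matrix, 'same' zero padding.

    Row order is (di, dj, c): all channels for one kernel offset are copied
    as one contiguous slab.
    """
    c, b, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.zeros((c, b, h + kh - 1, w + kw - 1), dtype=np.float32)
    xp[:, :, ph:ph + h, pw:pw + w] = x
    cols = np.empty((kh * kw, c, b * h * w), dtype=np.float32)
    cols5 = cols.reshape(kh * kw, c, b, h, w)
    for di in range(kh):
        for dj in range(kw):
            cols5[di * kw + dj] = xp[:, :, di:di + h, dj:dj + w]
    return cols.reshape(kh * kw * c, b * h * w)


def _wmat(weight: np.ndarray) -> np.ndarray:
    """(Cout, Cin, kh, kw) -> (Cout, kh*kw*Cin) matching the im2col row order."""
    cout, cin, kh, kw = weight.shape
    return np.ascontiguousarray(weight.transpose(0, 2, 3, 1)).reshape(cout, -1)


def _conv2d_forward_direct(x, weight, bias):
    cout, cin, kh, kw = weight.shape
    c, b, h, w = x.shape
    cols = _im2col(x, kh, kw)
    y = _wmat(weight) @ cols
    y += bias[:, None]
    return y.reshape(cout, b, h, w), ("direct", cols, weight, (b, h, w))


def _conv2d_backward_direct(dy, cache):
    _, cols, weight, (b, h, w) = cache
    cout, cin, kh, kw = weight.shape
    dyr = dy.reshape(cout, -1)
    dwr = dyr @ cols.T                            # (Cout, kh*kw*Cin)
    dweight = np.ascontiguousarray(
        dwr.reshape(cout, kh, kw, cin).transpose(0, 3, 1, 2)
    )
    dbias = dyr.sum(axis=1)
    # dx = dy (*) rot180(weight), channels swapped
    wf = weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin, Cout, kh, kw)
    dcols = _im2col(dy, kh, kw)                   # (kh*kw*Cout, BHW)
    dx = (_wmat(wf) @ dcols).reshape(cin, b, h, w)
    return dx, dweight, dbias


# ---- FFT path ---------------------------------------------------------------
# Correlations evaluated in the Fourier domain: irfft2(Af . conj(Bf))[m]
# equals sum_n a[n + m] b[n] for non-negative lags m, so the forward pass,
# the input gradient and the weight gradient are all per-frequency batched
# matmuls between transforms of (padded) activations, gradients and kernels.
# For the wide middle layers this replaces the k^2-fold im2col data
# duplication — the dominant cost on low-bandwidth hardware — with O(C^2 F)
# pointwise work, and the cache shrinks to the input transform.


def _fft_shape(n: int, k: int) -> int:
    return sfft.next_fast_len(n + k - 1, real=True)


def _conv2d_forward_fft(x, weight, bias):
    cout, cin, kh, kw = weight.shape
    c, b, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    hf, wf = _fft_shape(h, kh), _fft_shape(w, kw)
    xp = np.zeros((c, b, h + kh - 1, w + kw - 1), dtype=np.float32)
    xp[:, :, ph:ph + h, pw:pw + w] = x
    xf = sfft.rfft2(xp, s=(hf, wf))               # (Ci, B, hf, wf2)
    kf = sfft.rfft2(weight, s=(hf, wf))           # (Co, Ci, hf, wf2)
    nf2 = xf.shape[-1]
    f = xf.shape[-2] * nf2
    # per-frequency matmul: (F, B, Ci) @ (F, Ci, Co) -> (F, B, Co)
    xt = np.ascontiguousarray(xf.reshape(cin, b, f).transpose(2, 1, 0))
    kt = np.ascontiguousarray(np.conj(kf).reshape(cout, cin, f).transpose(2, 1, 0))
    yt = xt @ kt
    yf = yt.transpose(2, 1, 0).reshape(cout, b, xf.shape[-2], nf2)
    y = sfft.irfft2(yf, s=(hf, wf))[..., :h, :w].astype(np.float32)
    y += bias[:, None, None, None]
    return np.ascontiguousarray(y), ("fft", xt, kt, weight.shape, (b, h, w))


def _conv2d_backward_fft(dy, cache):
    _, xt, kt, wshape, (b, h, w) = cache
    cout, cin, kh, kw = wshape
    ph, pw = kh // 2, kw // 2
    hf, wf = _fft_shape(h, kh), _fft_shape(w, kw)
    dyf = sfft.rfft2(dy.astype(np.float32), s=(hf, wf))  # (Co, B, hf, wf2)
    nf2 = dyf.shape[-1]
    f = dyf.shape[-2] * nf2
    dyt = np.ascontiguousarray(dyf.reshape(cout, b, f).transpose(2, 1, 0))

    # dW[o, i, m] = sum_{b, n} xp[i, b, n + m] dy[o, b, n]
    dwt = np.conj(dyt).transpose(0, 2, 1) @ xt    # (F, Co, Ci)
    dwf = dwt.transpose(1, 2, 0).reshape(cout, cin, hf, nf2)
    dweight = np.ascontiguousarray(
        sfft.irfft2(dwf, s=(hf, wf))[..., :kh, :kw], dtype=np.float32
    )
    dbias = dy.sum(axis=(1, 2, 3))

    # dx[i] = sum_o corr(pad(dy_o), rot180(w[o, i])).  In the Fourier domain
    # the rotated kernel's conjugate transform is kt itself up to the phase
    # of the (kh-1, kw-1) index shift, so no kernel FFT is needed here.
    dyp = np.zeros((cout, b, h + kh - 1, w + kw - 1), dtype=np.float32)
    dyp[:, :, ph:ph + h, pw:pw + w] = dy
    dypf = sfft.rfft2(dyp, s=(hf, wf))
    dypt = dypf.reshape(cout, b, f).transpose(2, 1, 0)
    # conj(FT(rot180 w))[f] = conj(kt)[f]^T * exp(+2 pi i <f, k-1>/N)
    fh = np.arange(hf)[:, None]
    fw = np.arange(nf2)[None, :]
    phase = np.exp(2j * np.pi * ((kh - 1) * fh / hf + (kw - 1) * fw / wf))
    dypt = np.ascontiguousarray(
        dypt * phase.reshape(f)[:, None, None].astype(np.complex64)
    )
    dxt = dypt @ np.conj(kt.transpose(0, 2, 1))   # (F, B, Ci)
    dxf = dxt.transpose(2, 1, 0).reshape(cin, b, hf, nf2)
    dx = np.ascontiguousarray(
        sfft.irfft2(dxf, s=(hf, wf))[..., :h, :w], dtype=np.float32
    )
    return dx, dweight, dbias


#: kernels at least this large go through the FFT path.
_FFT_MIN_TAPS = 25


def conv2d_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """x: (Cin, B, H, W); weight: (Cout, Cin, kh, kw); returns (y, cache)."""
    cout, cin, kh, kw = weight.shape
    c, b, h, w = x.shape
    if c != cin:
        raise ValueError(f"input has {c} channels, kernel expects {cin}")
    if kh * kw >= _FFT_MIN_TAPS:
        return _conv2d_forward_fft(x, weight, bias)
    return _conv2d_forward_direct(x, weight, bias)


def conv2d_backward(dy: np.ndarray, cache):
    """dy: (Cout, B, H, W); returns (dx, dweight, dbias)."""
    if cache[0] == "fft":
        return _conv2d_backward_fft(dy, cache)
    return _conv2d_backward_direct(dy, cache)


def relu_forward(x: np.ndarray):
    y = np.maximum(x, 0.0)
    return y, y


def relu_backward(dy: np.ndarray, y: np.ndarray):
    return dy * (y > 0)


def dropout_forward(x: np.ndarray, rate: float, rng: np.random.Generator):
    """Inverted dropout: kept units scaled by 1/(1-rate)."""
    if rate <= 0:
        return x, None
    mask = (rng.random(x.shape, dtype=np.float32) >= rate) / np.float32(1.0 - rate)
    return x * mask, mask


def dropout_backward(dy: np.ndarray, mask):
    return dy if mask is None else dy * mask


def avgpool2_forward(x: np.ndarray):
    c, b, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("avgpool2 requires even spatial dimensions")
    y = x.reshape(c, b, h // 2, 2, w // 2, 2).mean(
        axis=(3, 5), dtype=np.float32
    )
    return y, (h, w)


def avgpool2_backward(dy: np.ndarray, cache):
    dx = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3)
    dx *= np.float32(0.25)
    return dx


def upsample2_forward(x: np.ndarray):
    y = np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)
    return y, x.shape


def upsample2_backward(dy: np.ndarray, cache):
    c, b, h, w = cache
    return dy.reshape(c, b, h, 2, w, 2).sum(axis=(3, 5), dtype=np.float32)
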