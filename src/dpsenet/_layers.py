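"""Minimal numpy layer primitives with hand-written backprop.

All tensors are batch-first NHWC float32. Convolutions are stride-1 with
"same" padding (odd kernels only), realised as im2col + GEMM so the heavy
lifting stays in BLAS. The backward pass for a convolution is itself a
convolution with the spatially flipped, channel-transposed kernel, which
keeps everything on the same fast path.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


# ---------------------------------------------------------------- convolution
# A same-padding stride-1 convolution is computed as one GEMM per kernel row:
# for each vertical offset dy, a width-direction sliding window over the
# padded input yields a (N·H·W, k·C_in) patch matrix whose inner (dx, c_in)
# block is contiguous in memory, so building it is a cheap blocked copy and
# the contraction runs in BLAS with a usefully large inner dimension.

def _padded(x: np.ndarray, k: int) -> np.ndarray:
    pad = k // 2
    return np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))


def _row_patches(xp: np.ndarray, dy: int, k: int, h: int) -> np.ndarray:
    """(N·H·W, k·C) patch matrix for kernel row dy of the padded input."""
    from numpy.lib.stride_tricks import sliding_window_view

    rows = xp[:, dy:dy + h]                       # (N, H, W+2p, C)
    win = sliding_window_view(rows, k, axis=2)    # (N, H, W, C, k)
    c = xp.shape[-1]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 3)).reshape(-1, k * c)


def conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray | None):
    """Same-padding stride-1 convolution. W has shape (k, k, C_in, C_out).

    Returns (output, padded_input); the padded input is the backward cache.
    """
    k, _, c_in, c_out = W.shape
    if k % 2 != 1:
        raise ValueError("same-padding convolution requires an odd kernel")
    n, h, w, _ = x.shape
    xp = _padded(x, k)
    out = np.zeros((n * h * w, c_out), dtype=DTYPE)
    for dy in range(k):
        out += _row_patches(xp, dy, k, h) @ W[dy].reshape(k * c_in, c_out)
    if b is not None:
        out += b
    return out.reshape(n, h, w, c_out), xp


def conv2d_backward(dout: np.ndarray, xp: np.ndarray, W: np.ndarray, need_dx: bool = True):
    """Gradients of conv2d given the cached padded input.

    Returns (dx, dW, db); dx is None when not requested.
    """
    k, _, c_in, c_out = W.shape
    n, h, w, _ = dout.shape
    dflat = dout.reshape(-1, c_out)
    dW = np.empty_like(W)
    for dy in range(k):
        dW[dy] = (_row_patches(xp, dy, k, h).T @ dflat).reshape(k, c_in, c_out)
    db = dflat.sum(axis=0)
    dx = None
    if need_dx:
        # full correlation of dout with the rotated kernel
        W_rot = np.ascontiguousarray(W[::-1, ::-1].transpose(0, 1, 3, 2))
        dx, _ = conv2d(dout, W_rot, None)
    return dx, dW, db


# -------------------------------------------------------------------- pooling

def maxpool2d(x: np.ndarray, p: int):
    n, h, w, c = x.shape
    if h % p or w % p:
        raise ValueError(f"spatial dims {h}x{w} not divisible by pool size {p}")
    xr = x.reshape(n, h // p, p, w // p, p, c)
    xf = np.ascontiguousarray(xr.transpose(0, 1, 3, 5, 2, 4)).reshape(n, h // p, w // p, c, p * p)
    idx = xf.argmax(axis=-1)
    out = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]
    return out, idx


def maxpool2d_backward(dout: np.ndarray, idx: np.ndarray, p: int, x_shape) -> np.ndarray:
    n, h, w, c = x_shape
    dxf = np.zeros((n, h // p, w // p, c, p * p), dtype=dout.dtype)
    np.put_along_axis(dxf, idx[..., None], dout[..., None], axis=-1)
    return np.ascontiguousarray(
        dxf.reshape(n, h // p, w // p, c, p, p).transpose(0, 1, 4, 2, 5, 3)
    ).reshape(n, h, w, c)


# ------------------------------------------------------------- dense and math

def dense(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    return x @ W + b


def dense_backward(dout: np.ndarray, x: np.ndarray, W: np.ndarray):
    return dout @ W.T, x.T @ dout, dout.sum(axis=0)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, y_onehot: np.ndarray, eps: float = 1e-7):
    """Mean cross-entropy over the batch plus the gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.sum(y_onehot * np.log(np.maximum(p, eps))) / n
    dlogits = (p - y_onehot) / n
    return float(loss), dlogits.astype(logits.dtype), p


# ------------------------------------------------------------------ optimizer

class Nadam:
    """Adam with Nesterov momentum (bias-corrected lookahead update)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        t = self.t
        for k, g in grads.items():
            m = self.m[k] = b1 * self.m[k] + (1 - b1) * g
            v = self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = m / (1 - b1 ** (t + 1))
            g_hat = g / (1 - b1 ** t)
            m_bar = (1 - b1) * g_hat + b1 * m_hat
            v_hat = v / (1 - b2 ** t)
            self.params[k] -= (self.lr * m_bar / (np.sqrt(v_hat) + self.eps)).astype(DTYPE)
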