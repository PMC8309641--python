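"""Numpy building blocks for the attention CNN: layers, CBAM, Adamax.

Everything here is functional: forward passes return ``(output, cache)`` and
backward passes consume ``(grad_output, cache)``.  Convolutions are stride-1
with same-padding, realised as im2col matrix products; gradients are exact
(verified against finite differences in the test suite).

The convolutional block attention module (CBAM) refines a feature map
``F (C x H x W)`` in two sequential stages:

* channel attention ``M_c = sigmoid(MLP(avgpool(F)) + MLP(maxpool(F)))``
  with a shared two-layer MLP (``W0: C -> C/r`` with ReLU, ``W1: C/r -> C``),
  pooling over the spatial dimensions;
* spatial attention ``M_s = sigmoid(f7x7([avgpool_c(F'); maxpool_c(F')]))``,
  a single 7x7 convolution over the channel-wise average and max maps.

``F' = M_c * F`` and ``F'' = M_s * F'`` with broadcasting; both gates are
strictly inside (0, 1), and CBAM never changes the tensor shape.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft

# ---------------------------------------------------------------------------
# elementwise activations


def relu(x):
    """max(0, x), elementwise; works on scalars and arrays."""
    return np.maximum(0, x)


def relu_grad(x):
    """Subgradient of ReLU: 1 where x > 0, else 0 (including at x = 0)."""
    x = np.asarray(x)
    dtype = x.dtype if x.dtype.kind == "f" else np.float64
    return (x > 0).astype(dtype)


def sigmoid(x):
    x = np.asarray(x)
    dtype = x.dtype if x.dtype.kind == "f" else np.float64
    out = np.empty_like(x, dtype=dtype)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# convolution (stride 1, same padding)


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """x: (N, C, H, W); w: (F, C, k, k) with odd k; b: (F,).

    Cross-correlation with zero same-padding; output (N, F, H, W).
    Evaluated spectrally (rfft2 of inputs and kernels, product summed over
    input channels): for 7x7 kernels this avoids materialising the k^2-fold
    im2col buffer, which dominates the cost for small batches.
    """
    n, c, h, wd = x.shape
    f, _, k, _ = w.shape
    p = k // 2
    fh = sfft.next_fast_len(h + 2 * p)
    fw = sfft.next_fast_len(wd + 2 * p)
    xf = sfft.rfft2(x, s=(fh, fw))
    wf_flip = sfft.rfft2(w[:, :, ::-1, ::-1], s=(fh, fw))
    yf = np.einsum("ncxy,fcxy->nfxy", xf, wf_flip)
    y = sfft.irfft2(yf, s=(fh, fw))[:, :, p : p + h, p : p + wd]
    out = y.astype(x.dtype, copy=False) + b.astype(x.dtype)[None, :, None, None]
    return out, (xf, w, x.shape, (fh, fw))


def conv2d_backward(dout: np.ndarray, cache):
    xf, w, xshape, (fh, fw) = cache
    n, c, h, wd = xshape
    f, _, k, _ = w.shape
    p = k // 2
    df = sfft.rfft2(dout, s=(fh, fw))
    # dx: full convolution of dout with the (un-flipped) kernels, channels
    # transposed — same 'same' slice as the forward pass
    wf = sfft.rfft2(w, s=(fh, fw))
    dxf = np.einsum("nfxy,fcxy->ncxy", df, wf)
    dx = sfft.irfft2(dxf, s=(fh, fw))[:, :, p : p + h, p : p + wd]
    # dw: cross-correlation of x with dout at lags -p..p (negative lags wrap
    # circularly; the zero padding keeps them uncontaminated)
    ccf = np.einsum("ncxy,nfxy->fcxy", xf, np.conj(df))
    cc = sfft.irfft2(ccf, s=(fh, fw))
    ih = (np.arange(k) - p) % fh
    iw = (np.arange(k) - p) % fw
    dw = cc[:, :, ih[:, None], iw[None, :]]
    db = dout.sum(axis=(0, 2, 3))
    return dx.astype(dout.dtype, copy=False), dw.astype(dout.dtype, copy=False), db


# ---------------------------------------------------------------------------
# 2x2 max pooling, stride 2


def maxpool_forward(x: np.ndarray):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool_backward(dout: np.ndarray, cache):
    idx, xshape = cache
    n, c, h, w = xshape
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx).reshape(n, c, h, w)


# ---------------------------------------------------------------------------
# dense / dropout / softmax cross-entropy


def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    return x @ w + b, (x, w)


def dense_backward(dout: np.ndarray, cache):
    x, w = cache
    return dout @ w.T, x.T @ dout, dout.sum(axis=0)


def dropout_forward(x: np.ndarray, rate: float, rng: np.random.Generator):
    """Inverted dropout: each unit dropped with probability ``rate``."""
    if rate == 0:
        return x, None
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
    return x * mask, mask


def dropout_backward(dout: np.ndarray, mask):
    return dout if mask is None else dout * mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    p = softmax(logits)
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


# ---------------------------------------------------------------------------
# CBAM


def _as_batch(x: np.ndarray):
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        return x[None], True
    if x.ndim == 4:
        return x, False
    raise ValueError(f"expected a (C,H,W) or (N,C,H,W) tensor, got shape {x.shape}")


def channel_attention_forward(x: np.ndarray, params: dict, prefix: str = ""):
    """Channel gate M_c (N, C, 1, 1) and the gated map; caches for backward.

    ``params`` holds ``{prefix}W0 (C, C/r)``, ``{prefix}b0``, ``{prefix}W1
    (C/r, C)``, ``{prefix}b1`` — the MLP shared between the average- and
    max-pooled descriptors.
    """
    w0, b0 = params[prefix + "W0"], params[prefix + "b0"]
    w1, b1 = params[prefix + "W1"], params[prefix + "b1"]
    n, c, h, wd = x.shape
    if w0.shape[0] != c:
        raise ValueError(
            f"channel-attention MLP expects {w0.shape[0]} channels, got {c}"
        )
    xf = x.reshape(n, c, h * wd)
    avg = xf.mean(axis=2)
    mx_idx = xf.argmax(axis=2)
    mx = np.take_along_axis(xf, mx_idx[..., None], axis=2)[..., 0]

    pre_a = avg @ w0 + b0
    hid_a = relu(pre_a)
    out_a = hid_a @ w1 + b1
    pre_m = mx @ w0 + b0
    hid_m = relu(pre_m)
    out_m = hid_m @ w1 + b1
    gate = sigmoid(out_a + out_m)  # (N, C)
    out = x * gate[:, :, None, None]
    cache = (x, avg, mx, mx_idx, pre_a, hid_a, pre_m, hid_m, gate, prefix, params)
    return out, gate, cache


def channel_attention_backward(dout: np.ndarray, cache):
    x, avg, mx, mx_idx, pre_a, hid_a, pre_m, hid_m, gate, prefix, params = cache
    w0, w1 = params[prefix + "W0"], params[prefix + "W1"]
    n, c, h, wd = x.shape
    dgate = (dout * x).sum(axis=(2, 3))
    dx = dout * gate[:, :, None, None]
    ds = dgate * gate * (1.0 - gate)

    grads = {}
    dvecs = []
    for hid, pre, vec in ((hid_a, pre_a, avg), (hid_m, pre_m, mx)):
        grads[prefix + "W1"] = grads.get(prefix + "W1", 0) + hid.T @ ds
        grads[prefix + "b1"] = grads.get(prefix + "b1", 0) + ds.sum(axis=0)
        dhid = (ds @ w1.T) * relu_grad(pre)
        grads[prefix + "W0"] = grads.get(prefix + "W0", 0) + vec.T @ dhid
        grads[prefix + "b0"] = grads.get(prefix + "b0", 0) + dhid.sum(axis=0)
        dvecs.append(dhid @ w0.T)
    davg, dmx = dvecs
    dx += davg[:, :, None, None] / (h * wd)
    dxf = dx.reshape(n, c, h * wd)
    ii, jj = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
    dxf[ii, jj, mx_idx] += dmx  # one argmax per (n, c): no index collisions
    return dxf.reshape(n, c, h, wd), grads


def spatial_attention_forward(x: np.ndarray, params: dict, prefix: str = ""):
    """Spatial gate M_s (N, 1, H, W) from a 7x7 conv over [avg_c; max_c]."""
    w, b = params[prefix + "W"], params[prefix + "b"]
    if w.shape[1] != 2:
        raise ValueError("spatial attention kernel must take 2 input planes")
    n, c, h, wd = x.shape
    avg = x.mean(axis=1, keepdims=True)
    mx_idx = x.argmax(axis=1)
    mx = np.take_along_axis(x, mx_idx[:, None], axis=1)
    desc = np.concatenate([avg, mx], axis=1)
    s, conv_cache = conv2d_forward(desc, w, b)
    gate = sigmoid(s)  # (N, 1, H, W)
    out = x * gate
    return out, gate, (x, mx_idx, gate, conv_cache, prefix)


def spatial_attention_backward(dout: np.ndarray, cache):
    x, mx_idx, gate, conv_cache, prefix = cache
    n, c, h, wd = x.shape
    dgate = (dout * x).sum(axis=1, keepdims=True)
    dx = dout * gate
    ds = dgate * gate * (1.0 - gate)
    ddesc, dw, db = conv2d_backward(ds, conv_cache)
    dx += ddesc[:, 0:1] / c
    ii = np.arange(n)[:, None, None]
    hh = np.arange(h)[None, :, None]
    ww = np.arange(wd)[None, None, :]
    dx[ii, mx_idx, hh, ww] += ddesc[:, 1]  # one argmax channel per pixel
    return dx, {prefix + "W": dw, prefix + "b": db}


def cbam_forward(x: np.ndarray, params: dict, prefix: str = ""):
    """F -> F'' through channel then spatial attention; shape preserved."""
    f1, _, ccache = channel_attention_forward(x, params, prefix + "ca_")
    f2, _, scache = spatial_attention_forward(f1, params, prefix + "sa_")
    return f2, (ccache, scache)


def cbam_backward(dout: np.ndarray, cache):
    ccache, scache = cache
    dmid, sgrads = spatial_attention_backward(dout, scache)
    dx, cgrads = channel_attention_backward(dmid, ccache)
    sgrads.update(cgrads)
    return dx, sgrads


# ---------------------------------------------------------------------------
# public single-tensor wrappers (convenience API mirroring the math)


def channel_attention(f: np.ndarray, params: dict) -> np.ndarray:
    """The channel attention map M_c for one (C, H, W) tensor, shape (C, 1, 1)."""
    x, single = _as_batch(f)
    _, gate, _ = channel_attention_forward(x, params)
    return gate[0][:, None, None] if single else gate[:, :, None, None]


def spatial_attention(f_prime: np.ndarray, params: dict) -> np.ndarray:
    """The spatial attention map M_s for one (C, H, W) tensor, shape (1, H, W)."""
    x, single = _as_batch(f_prime)
    _, gate, _ = spatial_attention_forward(x, params)
    return gate[0] if single else gate


def cbam(f: np.ndarray, params: dict) -> np.ndarray:
    """Apply the full attention block to a (C, H, W) or (N, C, H, W) tensor."""
    x, single = _as_batch(f)
    out, _ = cbam_forward(x, params)
    return out[0] if single else out


def init_cbam_params(
    channels: int,
    reduction: int,
    spatial_kernel: int,
    rng_for: "callable",
    prefix: str = "",
    dtype=np.float64,
) -> dict:
    """Seeded uniform fan-in initialisation of one CBAM block's parameters."""
    hidden = max(1, channels // reduction)
    params = {}

    def uni(name, shape, fan_in):
        bound = 1.0 / np.sqrt(fan_in)
        params[name] = rng_for(name).uniform(-bound, bound, size=shape).astype(dtype)

    uni(prefix + "ca_W0", (channels, hidden), channels)
    params[prefix + "ca_b0"] = np.zeros(hidden, dtype=dtype)
    uni(prefix + "ca_W1", (hidden, channels), hidden)
    params[prefix + "ca_b1"] = np.zeros(channels, dtype=dtype)
    uni(prefix + "sa_W", (1, 2, spatial_kernel, spatial_kernel), 2 * spatial_kernel**2)
    params[prefix + "sa_b"] = np.zeros(1, dtype=dtype)
    return params


# ---------------------------------------------------------------------------
# Adamax


class Adamax:
    """Adamax: Adam with an infinity-norm second moment.

    Update: ``m = b1 m + (1-b1) g``; ``u = max(b2 u, |g|)``;
    ``theta -= lr / (1 - b1^t) * m / (u + eps)``.
    """

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.u = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        corr = 1.0 - self.beta1**self.t
        for k, g in grads.items():
            m = self.m[k]
            u = self.u[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            np.maximum(self.beta2 * u, np.abs(g), out=u)
            params[k] -= (self.lr / corr) * m / (u + self.eps)
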