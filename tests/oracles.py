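"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written as plain loops / direct quadrature,
sharing no code with the implementations under test.
"""

from __future__ import annotations

import numpy as np


def cwt_quadrature(
    x: np.ndarray, sampling_rate: float, freqs: np.ndarray, omega0: float
) -> np.ndarray:
    """Direct numerical quadrature of the Morlet wavelet integral.

    W(a, tau) = 1/sqrt(a) * sum_t x(t) conj(psi((t - tau)/a)) dt with
    a = omega0 / (2 pi f), evaluated independently at every (frequency,
    shift) pair over the full (finite, zero-extended) signal.
    """
    n = len(x)
    t = np.arange(n) / sampling_rate
    dt = 1.0 / sampling_rate
    out = np.empty((len(freqs), n), dtype=complex)
    for i, f in enumerate(freqs):
        a = omega0 / (2.0 * np.pi * f)
        for j in range(n):
            u = (t - t[j]) / a
            psi = np.pi**-0.25 * np.exp(1j * omega0 * u) * np.exp(-0.5 * u**2)
            out[i, j] = np.sum(x * np.conj(psi)) * dt / np.sqrt(a)
    return out


def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def channel_attention_loops(f: np.ndarray, w0, b0, w1, b1) -> np.ndarray:
    """Channel gate for one (C, H, W) tensor, evaluated with straight loops."""
    c, h, w = f.shape
    avg = np.array([f[ch].sum() / (h * w) for ch in range(c)])
    mx = np.array([f[ch].max() for ch in range(c)])
    hidden = w0.shape[1]

    def mlp(v):
        hid = np.zeros(hidden)
        for q in range(hidden):
            s = b0[q]
            for ch in range(c):
                s += v[ch] * w0[ch, q]
            hid[q] = max(0.0, s)
        out = np.zeros(c)
        for ch in range(c):
            s = b1[ch]
            for q in range(hidden):
                s += hid[q] * w1[q, ch]
            out[ch] = s
        return out

    return _sigmoid(mlp(avg) + mlp(mx))  # (C,)


def spatial_attention_loops(f: np.ndarray, kernel, bias) -> np.ndarray:
    """Spatial gate for one (C, H, W) tensor via loop convolution.

    ``kernel`` is (1, 2, k, k): one filter over the channel-average and
    channel-max planes, same zero padding.
    """
    c, h, w = f.shape
    avg = f.mean(axis=0)
    mx = f.max(axis=0)
    k = kernel.shape[-1]
    p = k // 2
    gate = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            s = bias[0]
            for di in range(k):
                for dj in range(k):
                    ii, jj = i + di - p, j + dj - p
                    if 0 <= ii < h and 0 <= jj < w:
                        s += avg[ii, jj] * kernel[0, 0, di, dj]
                        s += mx[ii, jj] * kernel[0, 1, di, dj]
            gate[i, j] = _sigmoid(s)
    return gate  # (H, W)


def cbam_loops(f: np.ndarray, params: dict, prefix: str = "") -> np.ndarray:
    """F -> F'' for one (C, H, W) tensor via the loop references above."""
    mc = channel_attention_loops(
        f,
        params[prefix + "ca_W0"],
        params[prefix + "ca_b0"],
        params[prefix + "ca_W1"],
        params[prefix + "ca_b1"],
    )
    f1 = f * mc[:, None, None]
    ms = spatial_attention_loops(f1, params[prefix + "sa_W"], params[prefix + "sa_b"])
    return f1 * ms[None, :, :]


def band_power_welch(
    x: np.ndarray, sampling_rate: float, band: tuple[float, float]
) -> float:
    """Integrated Welch-periodogram power inside ``band`` (independent of the
    simulator's internals)."""
    from scipy.signal import welch

    nperseg = min(len(x), 512)
    f, p = welch(x, sampling_rate, nperseg=nperseg)
    mask = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(p[mask], f[mask]))
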