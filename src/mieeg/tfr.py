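"""Morlet continuous wavelet transform and classifier-image rendering.

The transform computes

.. math::

    W_x(a, \\tau) = \\frac{1}{\\sqrt{|a|}}
        \\int x(t)\\, \\psi^*\\!\\left(\\frac{t - \\tau}{a}\\right) dt

with the complex Morlet mother wavelet
:math:`\\psi(u) = \\pi^{-1/4} e^{i\\omega_0 u} e^{-u^2/2}` and the scale to
frequency map :math:`a(f) = \\omega_0 / (2\\pi f)` (seconds).  Power maps are
:math:`|W_x|^2` (optionally ``log1p``-compressed), and classifier inputs are
bilinear resizes of those maps to 64 x 64 pixels scaled into [0, 1].

The discrete transform is evaluated by FFT convolution with the sampled,
conjugate-reflected wavelet, truncated at five Gaussian widths (relative
truncation error ~ 4e-6).  Signals are implicitly zero-padded at the edges;
:func:`cone_of_influence` marks where that padding matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import fft as sfft
from skimage.transform import resize as _skimage_resize

#: Side length of the classifier input image.
IMAGE_SIZE = 64

#: Number of Gaussian widths at which the sampled wavelet is truncated.
_SUPPORT_WIDTHS = 5.0


def default_freqs() -> np.ndarray:
    """8-30 Hz in 0.5 Hz steps (45 analysis frequencies)."""
    return np.arange(8.0, 30.0 + 1e-9, 0.5)


@dataclass
class CwtConfig:
    """Analysis frequencies and Morlet parameters.

    ``omega0`` trades time against frequency resolution; 6 is the standard
    choice for EEG rhythms.  ``power_transform`` selects between straight
    energy (``"linear"``, :math:`|W|^2`) and compressed
    (``"log"``, :math:`\\log(1+|W|^2)`) power maps.
    """

    freqs: np.ndarray = field(default_factory=default_freqs)
    omega0: float = 6.0
    power_transform: str = "linear"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 1 or len(self.freqs) < 1:
            raise ValueError("freqs must be a non-empty 1-D sequence")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.freqs[0] <= 0:
            raise ValueError("freqs must be positive")
        if self.omega0 <= 0:
            raise ValueError("omega0 must be positive")
        if self.power_transform not in ("linear", "log"):
            raise ValueError("power_transform must be 'linear' or 'log'")

    def scales(self) -> np.ndarray:
        """Wavelet scales in seconds: a(f) = omega0 / (2 pi f)."""
        return self.omega0 / (2.0 * np.pi * self.freqs)


@dataclass
class TimeFrequencyMap:
    """Non-negative wavelet power on a frequency x time grid for one channel."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.shape != (len(self.freqs), len(self.times)):
            raise ValueError(
                f"power shape {self.power.shape} does not match "
                f"{len(self.freqs)} freqs x {len(self.times)} times"
            )
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class ClassifierImage:
    """A 64 x 64 single-plane image in [0, 1], ready for the CNN."""

    pixels: np.ndarray
    kind: str

    _KINDS = ("subtracted", "stacked", "map")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(
                f"classifier images are {IMAGE_SIZE} x {IMAGE_SIZE}; "
                f"got {self.pixels.shape}"
            )
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")


@lru_cache(maxsize=32)
def _kernel_bank_fft(
    freqs_key: tuple[float, ...], omega0: float, sampling_rate: float, n_signal: int
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """FFTs of the sampled wavelets at every analysis frequency.

    Returns ``(kernel_ffts, half_lengths, max_half, nfft)``; cached because
    the bank depends only on the grid, not on the signal.
    """
    freqs = np.asarray(freqs_key)
    dt = 1.0 / sampling_rate
    scales = omega0 / (2.0 * np.pi * freqs)
    halves = np.ceil(_SUPPORT_WIDTHS * scales / dt).astype(int)
    max_half = int(halves.max())
    nfft = sfft.next_fast_len(n_signal + 2 * max_half, real=False)
    bank = np.zeros((len(freqs), nfft), dtype=complex)
    for i, (a, half) in enumerate(zip(scales, halves)):
        k = np.arange(-half, half + 1)
        u = k * dt / a
        # psi*(-u) == psi(u) for the Morlet wavelet, so the correlation with
        # psi reduces to a convolution with this kernel.
        psi = np.pi**-0.25 * np.exp(1j * omega0 * u) * np.exp(-0.5 * u**2)
        kern = psi * dt / np.sqrt(a)
        # place kernel centre at index max_half so all rows share alignment
        padded = np.zeros(nfft, dtype=complex)
        padded[max_half - half : max_half + half + 1] = kern
        bank[i] = sfft.fft(padded)
    return bank, halves, max_half, nfft


def morlet_cwt(
    signal: np.ndarray, sampling_rate: float, config: CwtConfig | None = None
) -> np.ndarray:
    """Complex Morlet coefficients, shape ``(n_freqs, n_times)``.

    Row ``i`` holds :math:`W_x(a(f_i), \\tau)` on the input's own time grid.
    Frequencies at or above Nyquist are rejected.
    """
    if config is None:
        config = CwtConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    nyq = sampling_rate / 2.0
    if config.freqs[-1] >= nyq:
        raise ValueError(
            f"analysis frequency {config.freqs[-1]} Hz is at or above the "
            f"Nyquist frequency ({nyq} Hz)"
        )
    n = len(x)
    bank, _, max_half, nfft = _kernel_bank_fft(
        tuple(config.freqs), config.omega0, float(sampling_rate), n
    )
    xf = sfft.fft(x, nfft)
    full = sfft.ifft(bank * xf[None, :], axis=1)
    # kernel centres sit at index max_half of the padded kernels
    return full[:, max_half : max_half + n]


def power_map(
    coeffs: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    channel: str,
    power_transform: str = "linear",
) -> TimeFrequencyMap:
    """Wavelet power from complex coefficients (linear or log1p energy)."""
    p = np.abs(coeffs) ** 2
    if power_transform == "log":
        p = np.log1p(p)
    elif power_transform != "linear":
        raise ValueError("power_transform must be 'linear' or 'log'")
    return TimeFrequencyMap(power=p, freqs=freqs, times=times, channel=channel)


def cone_of_influence(freqs: np.ndarray, omega0: float = 6.0) -> np.ndarray:
    """Edge-effect half-width (s) per frequency: the wavelet truncation radius.

    Within this distance of either end of the signal, coefficients mix with
    the implicit zero padding.
    """
    freqs = np.asarray(freqs, dtype=float)
    return _SUPPORT_WIDTHS * omega0 / (2.0 * np.pi * freqs)


def _resize_bilinear(matrix: np.ndarray, out_size: int) -> np.ndarray:
    return _skimage_resize(
        matrix,
        (out_size, out_size),
        order=1,
        mode="edge",
        preserve_range=True,
        anti_aliasing=None,  # smooth only along downsampled axes
    )


def to_image(
    source: TimeFrequencyMap | np.ndarray,
    out_size: int = IMAGE_SIZE,
    kind: str = "map",
) -> ClassifierImage:
    """Bilinear-resize a power map to 64 x 64 and min-max scale into [0, 1].

    A constant input has no contrast to scale and maps to the neutral value
    0.5 everywhere.
    """
    m = source.power if isinstance(source, TimeFrequencyMap) else np.asarray(source)
    m = m.astype(float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError(f"need at least a 2 x 2 matrix to resize, got {m.shape}")
    resized = _resize_bilinear(m, out_size)
    lo, hi = resized.min(), resized.max()
    if hi - lo < 1e-12:
        pixels = np.full((out_size, out_size), 0.5)
    else:
        pixels = (resized - lo) / (hi - lo)
    return ClassifierImage(pixels=np.clip(pixels, 0.0, 1.0), kind=kind)
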