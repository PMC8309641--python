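"""Synthetic two-channel motor-imagery trials with ERD/ERS structure.

The simulator emulates the one feature the image-subtraction method exploits:
cue-locked, class-lateralised modulation of mu-band (8-13 Hz) and beta-band
(14-30 Hz) power on C3 versus C4, riding on 1/f background noise.

Laterality convention
---------------------
``label="left"``  => C3 band power *rises* (ERS) and C4 band power *falls*
(ERD); ``label="right"`` is the exact channel mirror.  This follows the
convention the classification method is built on.  Parts of the BCI
literature use the opposite (contralateral-ERD) convention; if you bring
your own data, check which one it follows before interpreting the sign of
subtracted images.

Generative model
----------------
Each channel is the sum of

* pink (1/f) noise with RMS ``noise_scale``,
* an amplitude-modulated mu sinusoid (centre ~10 +- 1 Hz, random phase),
* an amplitude-modulated beta sinusoid (centre ~22 +- 2 Hz, random phase).

During ``[cue_onset, cue_onset + mi_duration]`` the oscillation envelope of
the energy-falling channel is scaled so its band power drops by
``erd_depth`` (a power fraction), and the energy-rising channel so its band
power grows by ``ers_gain`` (a power factor).  Envelopes enter and leave the
modulated state through a 0.25 s raised-cosine ramp to avoid edge artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LABELS, EpochedTrial

#: Baseline amplitudes of the two sensorimotor rhythms, in the same arbitrary
#: units as ``noise_scale``.  The mu rhythm dominates, as over sensorimotor
#: cortex; beta is present but weaker.
MU_AMPLITUDE = 1.0
BETA_AMPLITUDE = 0.6

#: Raised-cosine ramp length (s) of the modulation envelope at cue onset/offset.
ENVELOPE_RAMP = 0.25


@dataclass
class SimConfig:
    """Parameters of the synthetic motor-imagery session.

    ``erd_depth`` is the fractional post-cue band-power attenuation on the
    energy-falling channel (0 = no ERD, 1 = complete suppression);
    ``ers_gain`` is the multiplicative post-cue band-power factor (>= 1) on
    the energy-rising channel.  Timing defaults mirror a standard cue-paced
    paradigm: 8 s trials, cue at 3 s, 4 s of imagery.
    """

    sampling_rate: float = 250.0
    trial_duration: float = 8.0
    cue_onset: float = 3.0
    mi_duration: float = 4.0
    mu_band: tuple[float, float] = (8.0, 13.0)
    beta_band: tuple[float, float] = (14.0, 30.0)
    erd_depth: float = 0.5
    ers_gain: float = 1.5
    noise_scale: float = 0.5
    n_trials_per_class: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu_band", "beta_band"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name} lower edge must be below upper edge")
        if self.cue_onset + self.mi_duration > self.trial_duration:
            raise ValueError("cue_onset + mi_duration must fit inside the trial")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.ers_gain < 1.0:
            raise ValueError("ers_gain must be >= 1")
        if self.sampling_rate <= 2.0 * self.beta_band[1]:
            raise ValueError("sampling_rate must exceed twice the upper beta edge")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.trial_duration))


def _pink_noise(rng: np.random.Generator, n: int, sampling_rate: float) -> np.ndarray:
    """Unit-RMS 1/f noise made by spectrally shaping white Gaussian noise."""
    n_freq = n // 2 + 1
    spectrum = rng.standard_normal(n_freq) + 1j * rng.standard_normal(n_freq)
    f = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    shape = np.zeros(n_freq)
    # 1/sqrt(f) amplitude shaping => 1/f power; flat below the first bin to
    # avoid a DC blow-up.
    nonzero = f > 0
    shape[nonzero] = 1.0 / np.sqrt(f[nonzero])
    x = np.fft.irfft(spectrum * shape, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _gain_envelope(
    times: np.ndarray, cue: float, duration: float, amp_gain: float
) -> np.ndarray:
    """Amplitude envelope: 1 at baseline, ``amp_gain`` during imagery.

    Raised-cosine transitions of length ``ENVELOPE_RAMP`` start at the cue
    and at the end of the imagery window.
    """
    env = np.ones_like(times)
    ramp = ENVELOPE_RAMP
    t0, t1 = cue, cue + duration
    rise = (times >= t0) & (times < t0 + ramp)
    env[rise] = 1.0 + (amp_gain - 1.0) * 0.5 * (
        1.0 - np.cos(np.pi * (times[rise] - t0) / ramp)
    )
    core = (times >= t0 + ramp) & (times < t1)
    env[core] = amp_gain
    fall = (times >= t1) & (times < t1 + ramp)
    env[fall] = amp_gain + (1.0 - amp_gain) * 0.5 * (
        1.0 - np.cos(np.pi * (times[fall] - t1) / ramp)
    )
    return env


def _channel_signal(
    rng: np.random.Generator, config: SimConfig, power_gain: float
) -> np.ndarray:
    """One channel: pink noise plus mu/beta oscillations with modulated envelope."""
    n = config.n_samples
    times = np.arange(n) / config.sampling_rate
    amp_gain = float(np.sqrt(power_gain))
    env = _gain_envelope(times, config.cue_onset, config.mi_duration, amp_gain)

    signal = np.zeros(n)
    for (lo, hi), amp, jitter in (
        (config.mu_band, MU_AMPLITUDE, 1.0),
        (config.beta_band, BETA_AMPLITUDE, 2.0),
    ):
        centre = 0.5 * (lo + hi)
        f0 = centre + rng.uniform(-jitter, jitter)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        signal += amp * env * np.sin(2.0 * np.pi * f0 * times + phase)
    if config.noise_scale > 0:
        signal += config.noise_scale * _pink_noise(rng, n, config.sampling_rate)
    return signal


def simulate_trial(
    config: SimConfig, label: str, rng: np.random.Generator | int | None = None
) -> EpochedTrial:
    """Generate one labelled trial.

    The rising-channel draws are always taken from ``rng`` before the
    falling-channel draws, so a left and a right trial generated from
    identically seeded generators are exact channel mirrors of each other.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rising = _channel_signal(rng, config, power_gain=config.ers_gain)
    falling = _channel_signal(rng, config, power_gain=1.0 - config.erd_depth)
    if label == "left":  # C3 rises, C4 falls
        data = np.stack([rising, falling])
    else:  # C4 rises, C3 falls
        data = np.stack([falling, rising])
    return EpochedTrial(
        data=data,
        sampling_rate=config.sampling_rate,
        cue_onset=config.cue_onset,
        label=label,
    )


def simulate_dataset(config: SimConfig) -> list[EpochedTrial]:
    """Generate a balanced, deterministically shuffled session of trials.

    Returns ``2 * n_trials_per_class`` trials; identical configs (including
    ``seed``) give bit-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    labels = ["left"] * config.n_trials_per_class + [
        "right"
    ] * config.n_trials_per_class
    trials = [simulate_trial(config, lab, rng) for lab in labels]
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]
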