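"""Preprocessing: channel selection, zero-phase band-pass, epoching, baseline.

The canonical order for a motor-imagery recording is::

    select_channels(rec, ["C3", "C4"])
    -> bandpass(rec, 8, 30)
    -> epoch_trials(rec, window=(-3, 4))
    -> baseline_correct(trial)

The band-pass is a 4th-order Butterworth applied forward-backward
(``sosfiltfilt``), so cue alignment is preserved exactly; epoch windows are
given in seconds relative to the cue.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import EpochedTrial, RawRecording

#: Default epoch window (s relative to cue): 3 s of pre-cue baseline and the
#: full 4 s imagery period.
DEFAULT_WINDOW = (-3.0, 4.0)

#: Default band for sensorimotor rhythms (mu + beta), Hz.
DEFAULT_BAND = (8.0, 30.0)


def select_channels(rec: RawRecording, names: list[str]) -> RawRecording:
    """Row-subset a recording to ``names`` (in that order); events unchanged."""
    missing = [n for n in names if n not in rec.channel_names]
    if missing:
        raise KeyError(
            f"channel(s) {missing} not in recording; available: {rec.channel_names}"
        )
    rows = [rec.channel_names.index(n) for n in names]
    return RawRecording(
        data=rec.data[rows].copy(),
        channel_names=list(names),
        sampling_rate=rec.sampling_rate,
        events=list(rec.events),
    )


def design_bandpass(low: float, high: float, sampling_rate: float) -> np.ndarray:
    """Second-order sections of the 4th-order Butterworth band-pass."""
    nyq = sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    return sps.butter(4, (low, high), btype="bandpass", fs=sampling_rate, output="sos")


def bandpass_data(
    data: np.ndarray, sampling_rate: float, low: float, high: float
) -> np.ndarray:
    """Zero-phase band-pass each row of ``data``; output length equals input."""
    sos = design_bandpass(low, high, sampling_rate)
    return sps.sosfiltfilt(sos, data, axis=-1)


def bandpass(rec: RawRecording, low: float, high: float) -> RawRecording:
    """Zero-phase Butterworth band-pass of every channel of a recording."""
    return RawRecording(
        data=bandpass_data(rec.data, rec.sampling_rate, low, high),
        channel_names=list(rec.channel_names),
        sampling_rate=rec.sampling_rate,
        events=list(rec.events),
    )


def epoch_trials(
    rec: RawRecording, window: tuple[float, float] = DEFAULT_WINDOW
) -> list[EpochedTrial]:
    """Cut one fixed-length trial per event.

    ``window`` is ``(start, end)`` in seconds relative to the cue; every
    trial has ``round((end - start) * fs)`` samples and carries its event's
    label.  The cue sits at ``-start`` seconds inside each trial.
    """
    start, end = window
    if start >= end:
        raise ValueError("epoch window start must precede its end")
    if list(rec.channel_names) != ["C3", "C4"]:
        raise ValueError(
            "epoching expects a two-channel (C3, C4) recording; "
            f"got channels {rec.channel_names} — apply select_channels first"
        )
    fs = rec.sampling_rate
    n_epoch = int(round((end - start) * fs))
    trials = []
    for i, (onset, label) in enumerate(rec.events):
        first = onset + int(round(start * fs))
        last = first + n_epoch
        if first < 0 or last > rec.n_samples:
            raise ValueError(
                f"event {i} (onset sample {onset}, label {label!r}): window "
                f"[{start}, {end}] s falls outside the recording"
            )
        trials.append(
            EpochedTrial(
                data=rec.data[:, first:last].copy(),
                sampling_rate=fs,
                cue_onset=-start,
                label=label,
            )
        )
    return trials


def baseline_correct(
    trial: EpochedTrial, baseline_window: tuple[float, float] | None = None
) -> EpochedTrial:
    """Subtract each channel's mean over ``baseline_window`` from the channel.

    The window is in seconds relative to the start of the trial and defaults
    to the pre-cue portion of the epoch.
    """
    if baseline_window is None:
        baseline_window = (0.0, trial.cue_onset)
    lo, hi = baseline_window
    fs = trial.sampling_rate
    first, last = int(round(lo * fs)), int(round(hi * fs))
    if not 0 <= first < last <= trial.n_samples:
        raise ValueError(
            f"baseline window {baseline_window} s is empty or outside the trial"
        )
    means = trial.data[:, first:last].mean(axis=1, keepdims=True)
    return EpochedTrial(
        data=trial.data - means,
        sampling_rate=fs,
        cue_onset=trial.cue_onset,
        label=trial.label,
    )


def preprocess_recording(
    rec: RawRecording,
    band: tuple[float, float] = DEFAULT_BAND,
    window: tuple[float, float] = DEFAULT_WINDOW,
    channels: tuple[str, str] = ("C3", "C4"),
) -> list[EpochedTrial]:
    """The full pipeline: select -> filter -> epoch -> baseline-correct."""
    rec = select_channels(rec, list(channels))
    rec = bandpass(rec, *band)
    return [baseline_correct(t) for t in epoch_trials(rec, window)]
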