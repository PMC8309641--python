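"""Shared containers for two-channel motor-imagery EEG.

The whole package is built around the sensorimotor electrode pair C3/C4:
every epoched trial carries exactly two channels in that fixed order, and
continuous recordings keep named channels plus cue events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The two classes of the binary motor-imagery task, in label-encoding order.
LABELS = ("left", "right")

#: Fixed channel order of an epoched trial.  C3 sits over the left
#: sensorimotor cortex, C4 over the right; the order is part of the contract
#: because the image-subtraction step is sign-sensitive.
TRIAL_CHANNELS = ("C3", "C4")


@dataclass
class EpochedTrial:
    """A fixed-length two-channel EEG segment around one motor-imagery cue.

    Parameters
    ----------
    data
        ``(2, n_samples)`` array of amplitudes (uV-scaled arbitrary units).
        Row 0 is C3, row 1 is C4 — always.
    sampling_rate
        Sampling frequency in Hz.
    cue_onset
        Cue time in seconds relative to the start of the segment.
    label
        ``"left"`` or ``"right"`` hand imagery.
    """

    data: np.ndarray
    sampling_rate: float
    cue_onset: float
    label: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 2:
            raise ValueError(
                f"trial data must be (2, n_samples) with rows (C3, C4); "
                f"got shape {self.data.shape}"
            )
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.cue_onset <= self.duration:
            raise ValueError("cue_onset must lie within the trial")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, with 0 at the start of the segment."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class RawRecording:
    """A continuous multichannel recording with cue events.

    ``events`` is a list of ``(onset_sample, label)`` pairs with strictly
    increasing onsets, all inside the recording.
    """

    data: np.ndarray
    channel_names: list[str]
    sampling_rate: float
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (n_channels, n_samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.events = [(int(on), str(lab)) for on, lab in self.events]
        onsets = [on for on, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        n = self.data.shape[1]
        for on, lab in self.events:
            if not 0 <= on < n:
                raise ValueError(f"event onset {on} outside recording of {n} samples")
            if lab not in LABELS:
                raise ValueError(f"event label must be one of {LABELS}, got {lab!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]
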