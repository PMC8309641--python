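"""Readers and writers for the package's plain-text data formats.

The on-disk layout of a dataset directory is:

* ``signals.csv`` — header row of channel names, one sample per row,
  floating-point amplitudes (a continuous recording; epoched trials are
  stored back-to-back).
* ``events.csv``  — columns ``onset_sample,label``; one row per cue.
* ``labels.tsv``  — two tab-separated columns ``trial_index,label``
  (written alongside simulated datasets for convenience).

Real recordings in EDF/GDF (e.g. the BCI Competition sets) can be adapted
through :func:`read_raw_edf_gdf`, which maps annotation codes onto the
package's ``left``/``right`` labels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import EpochedTrial, RawRecording

SIGNALS_FILE = "signals.csv"
EVENTS_FILE = "events.csv"
LABELS_FILE = "labels.tsv"


def write_recording(rec: RawRecording, out_dir: str | Path) -> dict[str, Path]:
    """Write a recording as ``signals.csv`` + ``events.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    signals_path = out_dir / SIGNALS_FILE
    events_path = out_dir / EVENTS_FILE
    pd.DataFrame(rec.data.T, columns=rec.channel_names).to_csv(
        signals_path, index=False, float_format="%.6f"
    )
    pd.DataFrame(rec.events, columns=["onset_sample", "label"]).to_csv(
        events_path, index=False
    )
    return {"signals": signals_path, "events": events_path}


def read_recording(data_dir: str | Path, sampling_rate: float) -> RawRecording:
    """Read a ``signals.csv`` + ``events.csv`` pair back into a recording.

    The CSV format carries no sampling rate, so it must be supplied (it is
    recorded in the resolved configuration of every run).
    """
    data_dir = Path(data_dir)
    signals = pd.read_csv(data_dir / SIGNALS_FILE)
    events_path = data_dir / EVENTS_FILE
    events: list[tuple[int, str]] = []
    if events_path.exists():
        ev = pd.read_csv(events_path)
        events = list(zip(ev["onset_sample"].astype(int), ev["label"].astype(str)))
    return RawRecording(
        data=signals.to_numpy().T,
        channel_names=list(signals.columns),
        sampling_rate=sampling_rate,
        events=events,
    )


def trials_to_recording(trials: list[EpochedTrial]) -> RawRecording:
    """Concatenate epoched trials back into one continuous recording.

    Cue events land at ``trial_start + cue_onset`` of each trial, so the
    preprocessing pipeline can re-epoch the written file.
    """
    if not trials:
        raise ValueError("cannot build a recording from zero trials")
    fs = trials[0].sampling_rate
    n = trials[0].n_samples
    for t in trials:
        if t.sampling_rate != fs or t.n_samples != n:
            raise ValueError("all trials must share sampling rate and length")
    data = np.concatenate([t.data for t in trials], axis=1)
    events = [
        (i * n + int(round(t.cue_onset * fs)), t.label) for i, t in enumerate(trials)
    ]
    return RawRecording(
        data=data, channel_names=["C3", "C4"], sampling_rate=fs, events=events
    )


def write_dataset(trials: list[EpochedTrial], out_dir: str | Path) -> dict[str, Path]:
    """Write trials as a continuous recording plus a ``labels.tsv`` sidecar."""
    rec = trials_to_recording(trials)
    paths = write_recording(rec, out_dir)
    labels_path = Path(out_dir) / LABELS_FILE
    pd.DataFrame(
        {"trial_index": range(len(trials)), "label": [t.label for t in trials]}
    ).to_csv(labels_path, sep="\t", index=False)
    paths["labels"] = labels_path
    return paths


def read_labels(path: str | Path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    return list(df["label"].astype(str))


def read_raw_edf_gdf(
    path: str | Path,
    event_map: dict[str, str],
    channel_map: dict[str, str] | None = None,
) -> RawRecording:
    """Adapter for EDF/GDF files (requires the optional ``mne`` dependency).

    Parameters
    ----------
    path
        ``.edf`` or ``.gdf`` file.
    event_map
        Maps annotation descriptions to ``"left"``/``"right"`` (for the
        BCI Competition IV-2b cue codes: ``{"769": "left", "770": "right"}``).
    channel_map
        Optional renaming applied before channel selection, for montages
        whose labels differ from plain ``C3``/``C4``.
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF/GDF files requires the optional 'mne' dependency "
            "(pip install mieeg[edf])"
        ) from err
    path = Path(path)
    if path.suffix.lower() == ".gdf":
        raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channel_map:
        raw.rename_channels(channel_map)
    events = []
    for onset, _, desc in zip(
        *_annotations_to_samples(raw), strict=True
    ):  # pragma: no cover
        if desc in event_map:
            events.append((onset, event_map[desc]))
    return RawRecording(
        data=raw.get_data(),
        channel_names=list(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        events=events,
    )


def _annotations_to_samples(raw):  # pragma: no cover - thin mne shim
    fs = float(raw.info["sfreq"])
    onsets = [int(round(a["onset"] * fs)) for a in raw.annotations]
    durations = [a["duration"] for a in raw.annotations]
    descs = [str(a["description"]) for a in raw.annotations]
    return onsets, durations, descs
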