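"""Hierarchical run configuration (YAML) and resolved-config echoing.

A config file has up to five sections mirroring the pipeline stages::

    sim:        {erd_depth: 0.7, noise_scale: 0.3, seed: 7, ...}
    preprocess: {band: [8, 30], window: [-3, 4]}
    tfr:        {freq_start: 8, freq_stop: 30, freq_step: 0.5, omega0: 6,
                 power_transform: linear}
    model:      {conv_filters: [32, 64], max_epochs: 200, ...}
    evaluation: {seed: 0, n_repetitions: 10, n_folds: 10}

Unset keys fall back to the package defaults; every run writes the fully
resolved configuration next to its results so it can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .model import ModelConfig
from .synth import SimConfig
from .tfr import CwtConfig

DEFAULT_EVALUATION = {"seed": 0, "n_repetitions": 10, "n_folds": 10}
DEFAULT_PREPROCESS = {"band": (8.0, 30.0), "window": (-3.0, 4.0)}


def load_config(path: str | Path | None) -> dict:
    """Read a YAML config file (or return an empty config)."""
    if path is None:
        return {}
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping of sections")
    return raw


def _tupled(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: tuple(v) if k in keys and v is not None else v for k, v in d.items()}


def resolve(config: dict) -> dict:
    """Fill every section with defaults; returns concrete config objects.

    Keys: ``sim`` (:class:`SimConfig`), ``preprocess`` (dict), ``tfr``
    (:class:`CwtConfig`), ``model`` (:class:`ModelConfig`), ``evaluation``
    (dict).
    """
    sim = SimConfig(**_tupled(config.get("sim", {}), ("mu_band", "beta_band")))
    pre = {**DEFAULT_PREPROCESS, **_tupled(config.get("preprocess", {}), ("band", "window"))}
    tfr_section = dict(config.get("tfr", {}))
    start = tfr_section.pop("freq_start", 8.0)
    stop = tfr_section.pop("freq_stop", 30.0)
    step = tfr_section.pop("freq_step", 0.5)
    cwt = CwtConfig(freqs=np.arange(start, stop + 1e-9, step), **tfr_section)
    model = ModelConfig(**_tupled(config.get("model", {}), ("conv_filters",)))
    evaluation = {**DEFAULT_EVALUATION, **config.get("evaluation", {})}
    return {
        "sim": sim,
        "preprocess": pre,
        "tfr": cwt,
        "model": model,
        "evaluation": evaluation,
    }


def dump_resolved(resolved: dict, path: str | Path) -> None:
    """Write the fully resolved configuration (all defaults made explicit)."""
    cwt: CwtConfig = resolved["tfr"]
    freqs = cwt.freqs
    out = {
        "sim": asdict(resolved["sim"]),
        "preprocess": {k: list(v) for k, v in resolved["preprocess"].items()},
        "tfr": {
            "freq_start": float(freqs[0]),
            "freq_stop": float(freqs[-1]),
            "freq_step": float(freqs[1] - freqs[0]) if len(freqs) > 1 else 0.0,
            "omega0": cwt.omega0,
            "power_transform": cwt.power_transform,
        },
        "model": asdict(resolved["model"]),
        "evaluation": dict(resolved["evaluation"]),
    }
    out["sim"]["mu_band"] = list(out["sim"]["mu_band"])
    out["sim"]["beta_band"] = list(out["sim"]["beta_band"])
    out["model"]["conv_filters"] = list(out["model"]["conv_filters"])
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
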