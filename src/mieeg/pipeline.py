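"""End-to-end plumbing: trials -> time-frequency maps -> images -> CV runs.

The three ablation variants differ only in two switches:

===============  =====================  ================
variant          classifier input       attention
===============  =====================  ================
UD-CNN           stacked (C3 over C4)   off
IS-CNN           subtracted (C3 - C4)   off
IS-CBAM-CNN      subtracted (C3 - C4)   on
===============  =====================  ================

:func:`run_ablation` evaluates any subset of variants on *identical* fold
assignments (same CV seeds), so their accuracies are paired fold by fold.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .core import EpochedTrial
from .evaluation import VARIANTS, EvaluationReport, cross_validate
from .model import CbamCnn, ModelConfig
from .preprocess import bandpass_data, baseline_correct
from .subtraction import image_subtract, stack_ud
from .tfr import CwtConfig, TimeFrequencyMap, morlet_cwt, power_map


def trial_to_maps(
    trial: EpochedTrial,
    cwt_config: CwtConfig | None = None,
    band: tuple[float, float] | None = (8.0, 30.0),
    baseline: bool = True,
) -> tuple[TimeFrequencyMap, TimeFrequencyMap]:
    """Per-channel wavelet power maps of one (optionally re-filtered) trial."""
    if cwt_config is None:
        cwt_config = CwtConfig()
    data = trial.data
    if band is not None:
        data = bandpass_data(data, trial.sampling_rate, *band)
    t = replace_data(trial, data)
    if baseline:
        t = baseline_correct(t)
    maps = []
    for row, channel in zip(t.data, ("C3", "C4")):
        coeffs = morlet_cwt(row, t.sampling_rate, cwt_config)
        maps.append(
            power_map(
                coeffs, cwt_config.freqs, t.times, channel, cwt_config.power_transform
            )
        )
    return maps[0], maps[1]


def replace_data(trial: EpochedTrial, data: np.ndarray) -> EpochedTrial:
    return EpochedTrial(
        data=data,
        sampling_rate=trial.sampling_rate,
        cue_onset=trial.cue_onset,
        label=trial.label,
    )


def featurize_trials(
    trials: list[EpochedTrial],
    variant: str = "IS-CBAM-CNN",
    cwt_config: CwtConfig | None = None,
    band: tuple[float, float] | None = (8.0, 30.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Classifier images ``(n, 64, 64)`` and labels for one variant.

    Featurisation is strictly per-trial, so it is fold-independent and can
    be computed once before cross-validation.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    combine = stack_ud if variant == "UD-CNN" else image_subtract
    images = []
    labels = []
    for trial in trials:
        m3, m4 = trial_to_maps(trial, cwt_config, band)
        images.append(combine(m3, m4).pixels)
        labels.append(trial.label)
    return np.stack(images), np.asarray(labels)


def variant_model_config(variant: str, base: ModelConfig | None = None) -> ModelConfig:
    """The model configuration for a variant (attention on/off)."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    base = base or ModelConfig()
    return replace(base, use_cbam=(variant == "IS-CBAM-CNN"))


def make_model_builder(config: ModelConfig):
    """A ``model_builder(seed)`` callable for :func:`~mieeg.evaluation.cross_validate`."""

    def build(seed: int) -> CbamCnn:
        return CbamCnn(replace(config, seed=int(seed)))

    return build


def run_variant(
    trials: list[EpochedTrial],
    variant: str,
    seed: int,
    model_config: ModelConfig | None = None,
    cwt_config: CwtConfig | None = None,
    n_repetitions: int = 10,
    n_folds: int = 10,
) -> EvaluationReport:
    """Featurise and cross-validate one variant."""
    images, labels = featurize_trials(trials, variant, cwt_config)
    cfg = variant_model_config(variant, model_config)
    return cross_validate(
        images,
        labels,
        make_model_builder(cfg),
        seed,
        n_repetitions=n_repetitions,
        n_folds=n_folds,
        variant=variant,
    )


def run_ablation(
    trials: list[EpochedTrial],
    variants=VARIANTS,
    seed: int = 0,
    model_config: ModelConfig | None = None,
    cwt_config: CwtConfig | None = None,
    n_repetitions: int = 10,
    n_folds: int = 10,
) -> list[EvaluationReport]:
    """Paired comparison of ablation variants (identical folds and seeds)."""
    for v in variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}; choose from {VARIANTS}")
    return [
        run_variant(
            trials, v, seed, model_config, cwt_config, n_repetitions, n_folds
        )
        for v in variants
    ]
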