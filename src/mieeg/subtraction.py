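"""Feature enhancement: C3 - C4 image subtraction, and the stacking baseline.

Because C3 and C4 sit mirror-symmetrically over the two sensorimotor
cortices, left- and right-hand imagery modulate their band power in opposite
directions.  Subtracting the C4 time-frequency map from the C3 map collapses
the two channels into one image whose *sign* encodes the lateralisation:
pixels above 0.5 mean more power at C3, below 0.5 more power at C4.

Subtraction operates on the power maps themselves (before any image
quantisation), and the difference is rescaled symmetrically about 0.5 so
that zero difference is always the neutral grey level — a per-trial
operation with no cross-trial statistics, hence no leakage across
cross-validation folds.

:func:`stack_ud` is the ablation baseline: the two maps are independently
min-max normalised and stitched vertically (C3 on top), discarding the sign
structure the subtraction preserves.
"""

from __future__ import annotations

import numpy as np

from .tfr import IMAGE_SIZE, ClassifierImage, TimeFrequencyMap, _resize_bilinear


def _check_axes(map_a: TimeFrequencyMap, map_b: TimeFrequencyMap) -> None:
    if map_a.power.shape != map_b.power.shape:
        raise ValueError(
            f"map shapes differ: {map_a.power.shape} vs {map_b.power.shape}"
        )
    if not (
        np.allclose(map_a.freqs, map_b.freqs) and np.allclose(map_a.times, map_b.times)
    ):
        raise ValueError("maps must share identical frequency and time axes")


def _check_channel_order(map_c3: TimeFrequencyMap, map_c4: TimeFrequencyMap) -> None:
    if map_c3.channel != "C3" or map_c4.channel != "C4":
        raise ValueError(
            f"image_subtract takes (C3, C4) in that order; got "
            f"({map_c3.channel!r}, {map_c4.channel!r}) — a silent sign flip "
            f"would swap the class encoding"
        )


def power_difference(
    map_a: TimeFrequencyMap, map_b: TimeFrequencyMap
) -> np.ndarray:
    """Raw pixel-wise power difference ``A - B`` on the native grid."""
    _check_axes(map_a, map_b)
    return map_a.power - map_b.power


def image_subtract(
    map_c3: TimeFrequencyMap, map_c4: TimeFrequencyMap
) -> ClassifierImage:
    """The subtracted classifier input.

    ``D = P(C3) - P(C4)`` is mapped through ``v -> 0.5 + v / (2 max|D|)``
    (so 0.5 encodes zero difference and the sign survives), then
    bilinear-resized to 64 x 64.  Identical maps yield the uniform neutral
    image.
    """
    _check_channel_order(map_c3, map_c4)
    d = power_difference(map_c3, map_c4)
    m = np.abs(d).max()
    scaled = np.full_like(d, 0.5) if m == 0 else 0.5 + d / (2.0 * m)
    pixels = np.clip(_resize_bilinear(scaled, IMAGE_SIZE), 0.0, 1.0)
    return ClassifierImage(pixels=pixels, kind="subtracted")


def _minmax(m: np.ndarray) -> np.ndarray:
    lo, hi = m.min(), m.max()
    if hi - lo < 1e-12:
        return np.full_like(m, 0.5)
    return (m - lo) / (hi - lo)


def stack_ud(map_c3: TimeFrequencyMap, map_c4: TimeFrequencyMap) -> ClassifierImage:
    """The up-down stacking baseline: C3 above C4, each normalised alone."""
    _check_axes(map_c3, map_c4)
    stacked = np.vstack([_minmax(map_c3.power), _minmax(map_c4.power)])
    pixels = np.clip(_resize_bilinear(stacked, IMAGE_SIZE), 0.0, 1.0)
    return ClassifierImage(pixels=pixels, kind="stacked")
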