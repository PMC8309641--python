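# mieeg

Classification of left- versus right-hand motor imagery from two-channel
EEG, built around a simple observation: the C3 and C4 electrodes sit
mirror-symmetrically over the two sensorimotor cortices, and imagining a
hand movement drives their mu-band (8–13 Hz) and beta-band (14–30 Hz)
power in *opposite* directions (event-related desynchronisation /
synchronisation, ERD/ERS).  Subtracting the C4 time–frequency map from the
C3 map therefore collapses a trial into one image whose sign structure
encodes the imagined hand — a representation a small CNN can classify
directly.

The package is aimed at BCI researchers and students who want a compact,
fully inspectable reference implementation of this pipeline, testable end
to end without any external recordings.

## The method

For each trial (channels C3, C4; band-passed 8–30 Hz, zero phase;
baseline-corrected):

1. **Morlet CWT** per channel:
   W<sub>x</sub>(a, τ) = |a|<sup>−1/2</sup> ∫ x(t) ψ*((t − τ)/a) dt with
   ψ(u) = π<sup>−1/4</sup> e<sup>iω₀u</sup> e<sup>−u²/2</sup>,
   a(f) = ω₀/(2πf), ω₀ = 6; power maps |W|² on a 8–30 Hz grid.
2. **Image subtraction (IS)**: D = P(C3) − P(C4), rescaled by
   v ↦ 0.5 + v/(2·max|D|) and resized to 64 × 64 — pixel > 0.5 means more
   power at C3.  (The ablation baseline stacks the two maps vertically
   instead.)
3. **CNN with CBAM attention**: two 7×7 conv + 2×2 max-pool stages with a
   convolutional block attention module (channel gate
   σ(MLP(avgpool) + MLP(maxpool)), then spatial gate σ(f⁷ˣ⁷[avg; max]))
   after each convolution; dropout; softmax head; Adamax, lr 3·10⁻⁴.
4. **Evaluation**: accuracy and Cohen's kappa
   κ = (p₀ − p<sub>e</sub>)/(1 − p<sub>e</sub>) with p<sub>e</sub> = 0.5,
   under 10 × 10-fold stratified cross-validation.

A bundled simulator generates labelled two-channel trials with exactly this
ERD/ERS structure (1/f noise + amplitude-modulated mu/beta oscillations,
`left` ⇒ C3 power rises / C4 falls, mirrored for `right`), so the whole
chain is testable offline.  See `docs/methods.md` for assumptions,
parameter choices and limitations.

## A worked example

```python
import numpy as np
from mieeg import SimConfig, simulate_trial, image_subtract
from mieeg.pipeline import trial_to_maps

trial = simulate_trial(SimConfig(erd_depth=0.75, ers_gain=1.5,
                                 noise_scale=0.2), "left", rng=5)
m3, m4 = trial_to_maps(trial)          # 45 x 2000 wavelet power maps
image = image_subtract(m3, m4)         # 64 x 64, neutral level 0.5
mu = image.pixels[0:15]                # rows covering 8-13 Hz
print(round(mu[:, 0:22].mean(), 3))    # pre-cue        -> 0.494
print(round(mu[:, 27:56].mean(), 3))   # imagery window -> 0.719
```

Before the cue the mu-band region of the subtracted image sits at the
neutral level (0.494 ≈ 0.5: neither hemisphere dominates); during imagery
it rises to 0.719, the left-hand signature (C3 power above C4).  Training
the attention CNN on such images and cross-validating recovers the class:

```sh
python examples/04_crossval_ablation.py
```

prints paired cross-validated accuracy and kappa for the three variants
(stacked input without attention, subtracted input without attention, and
subtracted input with attention) — on the example's clearly lateralised
session all three reach `1.000 ± 0.000`; the subtracted representation's
advantage shows up as a larger between-class contrast and, on noisier
data, higher paired accuracy.
Each `examples/*.py` script exercises one capability and explains its
output; the `mieeg` command (`simulate`, `run`, `render`) drives the same
pipeline from the shell with a YAML configuration and writes a fully
resolved config next to every result.

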