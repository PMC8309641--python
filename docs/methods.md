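# Methods

## The problem and the approach

Left- versus right-hand motor imagery modulates the sensorimotor rhythms
recorded over the two hemispheres: band-limited power in the mu (8–13 Hz)
and beta (14–30 Hz) rhythms falls on one side (event-related
desynchronisation, ERD) and rises on the other (event-related
synchronisation, ERS), cue-locked and lateralised by the imagined hand.
Because the C3 and C4 electrodes sit mirror-symmetrically over the two
sensorimotor cortices, the two classes produce opposite power patterns on
the pair.

The pipeline implemented here classifies single trials in four stages:

1. **Preprocessing** — select C3/C4, band-pass 8–30 Hz with a 4th-order
   Butterworth applied forward–backward (zero phase, so cue timing is
   untouched), epoch around the cue, and subtract each channel's pre-cue
   mean (baseline correction).
2. **Time–frequency imaging** — continuous Morlet wavelet transform

   W<sub>x</sub>(a, τ) = |a|<sup>−1/2</sup> ∫ x(t) ψ*((t−τ)/a) dt,
   ψ(u) = π<sup>−1/4</sup> e<sup>iω₀u</sup> e<sup>−u²/2</sup>,
   a(f) = ω₀ / (2πf),

   evaluated on a frequency grid covering 8–30 Hz; power is |W|².
3. **Image subtraction (IS)** — the C4 power map is subtracted pixel-wise
   from the C3 map, rescaled symmetrically about 0.5 and resized to the
   64 × 64 classifier input.  One image per trial; the *sign* of each pixel
   (above/below 0.5) encodes which hemisphere carried more power.
4. **Classification** — a small CNN (two 7×7 convolution + 2×2 max-pool
   stages, a convolutional block attention module after each convolution,
   dropout, one fully connected softmax head) trained with Adamax at
   learning rate 3·10⁻⁴ on cross-entropy.

Evaluation uses accuracy and Cohen's kappa with chance level p<sub>e</sub> = 0.5
(balanced binary task), so kappa = 2·accuracy − 1, under 10 repetitions of
stratified 10-fold cross-validation.

## The synthetic-data generator

No public EEG is bundled; every stage is exercised on a simulator that
produces exactly the structure the subtraction step exploits:

* per channel, pink (1/f) noise (spectrally shaped white noise, unit RMS
  scaled by `noise_scale`) plus one mu (centre 10.5 ± 1 Hz) and one beta
  (22 ± 2 Hz) sinusoid with random phase per trial;
* during the imagery window the oscillation envelope of the energy-falling
  channel is scaled to (1 − `erd_depth`)<sup>1/2</sup> and the rising
  channel to `ers_gain`<sup>1/2</sup>, so *band power* changes by those
  factors; envelopes ramp over 0.25 s raised cosines to avoid spectral
  edge artifacts;
* laterality: `left` raises C3 and lowers C4; `right` is the exact channel
  mirror (the rising-channel random draws are consumed first, so equal
  seeds give exactly mirrored trials — a property the tests use).

Defaults: 250 Hz, 8 s trials, cue at 3 s, 4 s imagery, `erd_depth` 0.5,
`ers_gain` 1.5, `noise_scale` 0.5 (oscillation amplitudes 1.0 / 0.6 for
mu / beta).  These are free parameters of the simulator, chosen to give a
clearly detectable but noisy modulation; real recordings show comparable
fractional band-power changes but the simulator deliberately omits volume
conduction, ocular/muscular artifacts, inter-trial non-stationarity and
inter-subject variability.  Passing tests therefore demonstrate that the
pipeline recovers the lateralisation structure it targets, not that any
particular accuracy transfers to real data.

## Numerical choices

* **CWT** — FFT convolution with the sampled wavelet truncated at five
  Gaussian widths (relative truncation error ≈ 4·10⁻⁶); signals are
  implicitly zero-padded, and `cone_of_influence` reports the per-frequency
  edge radius.  ω₀ = 6 by default; the frequency grid is 8–30 Hz in 0.5 Hz
  steps (45 rows).  The implementation is verified against direct
  quadrature of the transform integral to < 10⁻³ relative error.
* **Resizing** — bilinear (`skimage.transform.resize`, order 1) with
  anti-aliasing along downsampled axes; min–max scaling to [0, 1]; a
  constant matrix maps to the neutral value 0.5.
* **Subtraction** — operates on power maps *before* any quantisation, and
  rescales by v ↦ 0.5 + v / (2·max|D|) rather than per-image min–max, so
  zero difference is always 0.5 and the lateralisation sign survives.  All
  normalisation is per-trial: no statistic crosses trials, hence none
  crosses cross-validation folds.
* **CNN** — implemented in numpy.  Convolutions are stride-1, same-padded
  7×7 kernels evaluated spectrally (rfft2 products summed over input
  channels) — substantially faster than im2col at the small batch sizes
  used here; gradients (including both attention gates, whose max-pool
  branches route gradients to argmax positions) are exact and
  finite-difference-checked in the tests.  Weight init is seeded uniform
  fan-in; every parameter draws from its own named stream, so toggling the
  attention module off leaves all shared layers' initialisation unchanged —
  that makes "CBAM bypassed" bit-identical to the no-attention variant, an
  equivalence the tests assert.
* **Dropout** — the fixed design constant 0.8 is read as the *drop*
  probability (inverted dropout, active only in training).  It is exposed
  on `ModelConfig` because the other reading (keep probability 0.8) exists
  in older frameworks.
* **Adamax** — β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸, first-moment bias
  correction; learning rate 3·10⁻⁴.
* **Cross-validation** — repetition r shuffles with seed `seed + r`
  (stratified folds); the summary std is the sample std across the 10
  repetition means, not across the 100 folds — the less optimistic
  choice.  Fold assignments depend only on the labels and seed, so ablation
  variants run on identical folds and are compared paired.

## Architecture hyperparameters

Fixed by design: 7×7 convolution kernels, 2×2 stride-2 max pooling, CBAM
after each convolution (a `cbam_placement="first"` switch restricts it to
the first block), 7×7 spatial-attention kernel, dropout 0.8, Adamax at
3·10⁻⁴, binary softmax head directly on the flattened features.

Free (defaults in parentheses): filter counts (32, 64), channel-attention
reduction ratio (16), batch size (32), max epochs (200) with patience-20
early stopping on a held-out split when `validation_fraction` > 0.

## Problem sizes used in the checked experiments

The end-to-end suite simulates one session of 120 trials with strong,
low-noise modulation (`erd_depth` 0.75, `ers_gain` 1.5, `noise_scale` 0.2,
seed 7) and trains a reduced network — filters (4, 8), reduction 2, batch
4, 14 epochs, no early stopping — chosen from a convergence pilot on the
training loss so that each fold trains to separation quickly on one CPU.
The subtraction + attention pipeline runs the full 10 × 10-fold grid; the
two ablation baselines and the label-shuffle control run 3 × 10 and 2 × 10
folds respectively on identical fold seeds.  Under these conditions the
full pipeline reaches mean accuracy ≥ 0.9, the shuffle control sits at
chance, and the subtracted representation is at least as accurate as
up-down stacking.

## Known limitations

* The published per-subject accuracies on the BCI Competition datasets are
  not reproduced here: they require the original recordings (EDF/GDF
  downloads) and carry subject-level variability; the package ships the
  published numbers as data (`mieeg.published`) and recomputes only their
  internal arithmetic (kappa mapping, table aggregation).  An EDF/GDF
  adapter (`mieeg.io.read_raw_edf_gdf`, optional `mne` dependency) is the
  seam for running the identical pipeline on the real data.
* One published aggregate is arithmetically inconsistent with its own
  table: the BP-SVM per-subject accuracies average to 70.29%, printed as
  70.2%, which propagates to the "9.4%" improvement figure (the table
  arithmetic gives 9.3%).  The aggregator computes from per-subject values
  and is tested to printed precision ± one unit in the last digit.
* The method is defined only for the logically symmetric C3/C4 pair;
  subtraction of arbitrary channel pairs is out of scope.
* Alternative time-frequency front-ends (short-time Fourier, Hilbert–Huang)
  are deliberately not implemented; `trial_to_maps` is the seam where one
  would plug them in.
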