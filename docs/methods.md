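# Methods

## Signal model

A mosquito transit through the optical sensing zone is modelled as an
amplitude burst inside a fixed-length record of `N = 1024` samples at
`fs = 9603` samples/s (≈107 ms):

```
x(t) = clip( HP300[ A · env(t) · Σ_k a_k sin(2π k f1 t + φ_k) ] + n(t) − mean )
```

- `f1` is the wingbeat fundamental, drawn per recording from the class's
  normal distribution; harmonics at `k·f1` (k = 2, 3, 4) carry amplitude
  ratios `a_k` relative to the fundamental, with independent uniform
  phases. Synthesis refuses profiles whose highest harmonic would exceed
  the Nyquist frequency (4801.5 Hz).
- `env(t)` is a Tukey (α = 0.5) window of the drawn event duration
  (default ~N(50, 10) ms, floored at 5 ms and capped at the record
  length), placed uniformly at random so the whole event fits in the
  record. A 50 ms event therefore occupies ≈480 of the 1024 samples.
- `A` is set so that the Welch peak density at `f1` of a *sustained* tone
  would equal the drawn peak power: `A = sqrt(2 · 10^(P/10) · ENBW)` with
  the Hann equivalent noise bandwidth `ENBW = 1.5 · fs / 512`. Because the
  envelope gates the tone off for part of the record, the *measured* peak
  power of a simulated flight sits a few dB below the drawn value; the
  offset is common to all classes, so class geometry is preserved.
- `HP300` is the receiver high-pass: a 2nd-order Butterworth at 300 Hz
  applied forward–backward (zero phase). The bidirectional pass is the
  natural choice in simulation (no causality constraint) and gives ≈38 dB
  rejection at 100 Hz and complete DC removal, comfortably beyond the
  >20 dB low-frequency rejection the sensor requires.
- `n(t)` is sensor noise: white noise at the above-300 Hz floor density
  plus, in the default `filtered` model, an extra low-band component
  confined below 300 Hz by a 6th-order Butterworth low-pass at 250 Hz.
  Defaults (−88 dB/Hz below 300 Hz, −93 dB/Hz above) sit ~3 dB below the
  published bounds (−85/−90 dB/Hz) so that *estimated* floors, which
  fluctuate upward of the target by a fraction of a dB, still respect the
  bounds. The steep low-pass keeps low-band leakage just above 300 Hz more
  than 5 dB under the high-band floor.
- Baseline correction (mean subtraction) and clipping to the ADC's
  [−1, 1] full scale close the chain.

Invalid events — the kind excluded on manual review — are simulated as
either two overlapping flights (second f1 jittered ±80 Hz) or a broadband
transient spike, and flagged `valid=false`. Corpus generation flags each
recording independently with the configured probability (default 2.3%).

Timestamps are deterministic (90 s cadence from a fixed epoch) so that
identical seeds give byte-identical corpora; ambient temperature metadata
is drawn from N(25.8, 1.2) °C and is not used by any model.

## Default class profiles

The real corpus is private and no per-class distribution parameters are
published, so the defaults are synthetic stand-ins calibrated to the
published **qualitative** structure, chosen once:

| class | f1 (Hz) | peak power (dB/Hz) | harmonics a₂,a₃,a₄ |
|---|---|---|---|
| *Aedes* female | N(550, 40) | N(−53, 5) | 0.5, 0.25, 0.12 |
| *Aedes* male | N(800, 50) | N(−58, 5) | 0.5, 0.25, 0.12 |
| *Culex* female | N(380, 30) | N(−57, 5) | 0.3, 0.5, 0.15 |
| *Culex* male | N(620, 40) | N(−62, 5) | 0.3, 0.5, 0.15 |

Three facts of the published results drive this calibration: sexes within
a genus separate strongly in f1 while the genera overlap (*Aedes* female
vs *Culex* male); peak power **alone** is a usable genus discriminant
(~70% in the real data), so power carries a genus offset (≈4 dB,
*Aedes* louder) on top of the within-genus sex offset (≈5 dB, females
louder); and full-spectrum features outperform the scalar f1 feature by a
wide margin, so wingbeat *timbre* — the harmonic balance — differs by
genus (*Culex* profiles emphasize the second harmonic). Both *Aedes*
species share one set of signal statistics but distinct labels, so
species-level bookkeeping (quotas, stratification) is exercised.

What the simulator does **not** emulate: within-event frequency
modulation, temperature dependence of f1, body-size variation, age and
parity effects, species-level differences, and any optical/geometric
detail of the sensor. Passing benches on this corpus therefore
demonstrate that the pipeline's machinery is correct and that it recovers
a known class geometry — not that real field accuracy would match.

## Feature extraction

- **Welch PSD**: 512-sample Hann windows, 50% overlap (three segments per
  record), periodograms averaged, one-sided density scaling → 257 values.
  dB values are `10·log10(density / 1.0 unit²/Hz)`, so unit-density white
  noise sits at 0 dB/Hz. The 50% overlap is the conventional Welch
  default; only the window length (and hence the 257-bin grid) is fixed
  by the sensor's processing chain.
- **f1 / peak power**: global maximum of the PSD within 300–900 Hz, ties
  broken toward the lower frequency, no sub-bin interpolation. The bin
  width is fs/512 ≈ 18.8 Hz; median recovery error on noisy simulated
  flights is ~5 Hz.
- **Spectrogram**: nine 512-sample segments at hop 64 (segment k covers
  samples [64k, 64k+512)), Hann window, one-sided amplitude spectra.
  Models consume it flattened (2313 values) in log-power scale by
  default; linear amplitude/power are configurable, since the scale used
  originally is not documented.
- **MFCC**: per segment, power spectrum → 16 overlapping triangular Mel
  filters (centres equally spaced in mel(f) = 2595·log10(1 + f/700)
  between 0 Hz and Nyquist, unit peak) → natural log with an additive
  floor of 1e−12 (silent segments stay finite and equal) → orthonormal
  DCT-II as the cepstral transform, the standard realization of the
  inverse transform of a real, even log-spectrum. 9×16 = 144
  coefficients, all kept. Under a pure gain g only coefficient 0 moves
  (by √16·ln g²); coefficients 1–15 are gain-invariant.

## Protocol

Validity filtering is flag-driven (the human review itself is out of
scope). Balancing randomly under-samples each stratum (species × sex by
default) to the smallest stratum, a fixed quota, or per-stratum quotas —
quotas are explicit config because the published balanced corpora do not
always use the minimum (the *Culex* sex set used 780 of 899 available
males). The 75/25 split and the four CV folds are stratified by class
label so the balanced design survives partitioning; a flag restores the
purely random split. Fold sizes differ by at most one when counts do not
divide evenly (e.g. a 1170-recording training set folds as
293/293/292/292).

## Bench

LR, SVM and DNN pipelines standardize features column-wise with
statistics fitted on the training rows of the round at hand; tree
ensembles (gradient boosting, random forests) run on raw features. The
DNN is a fully connected 64→32 ReLU network with early stopping on an
internal 15% holdout of its training rows, learning rate 0.01, ≤500
epochs. Gradient boosting uses 60 histogram trees of depth 3 at learning
rate 0.2; the SVM is RBF with C = 10, γ = scale; LR uses C = 1. Default
grids hold a single configuration per algorithm — the winning
hyperparameters of the original study are not published, and one
documented configuration keeps the 3-task × 6-feature × 5-algorithm bench
at desk scale — while multi-configuration grids are plain config inputs
and the CV selection path (best mean fold accuracy, ties to the earlier =
simpler configuration) is exercised in tests.

The error analysis maps the best cell's (training, validation) accuracy
pair to a verdict: both perfect → `no_error`; training exceeding
validation by more than 0.03 → `overfit_more_samples`; training below
0.90 → `underfit_more_capacity`; otherwise `no_overfitting`. The cascade
applies the genus model first, then the predicted genus's sex model; it
is a composition of the three separately trained tasks, so its joint
accuracy is bounded by its weakest stage.

## Problem sizes and reproducibility

Default study conditions: 150 recordings per class profile (six profiles,
900 recordings), 2.3% invalid, noise floors at −88/−93 dB/Hz. Bench-level
acceptance checks average grid cells over three independently simulated
corpora (seeds derived from the run seed), which at ~150-recording test
sets gives accuracy orderings whose margins (2–9 points) clearly exceed
the ~1-point standard error of the mean. Dimensional and protocol
arithmetic (257/9/144 values; 2688 → 2016/672, 1344 → 1008/336,
1560 → 1170/390) is exact and seed-independent. Every stochastic
component — synthesis, balancing, splitting, folding, model seeds — takes
an explicit seed, and identical seeds produce bit-identical corpora and
fitted models.

## Known limitations

- Peak power is reported at the PSD bin maximum without envelope
  (duty-cycle) compensation, so simulated flights read a few dB below
  their drawn peak power; only between-class contrasts are meaningful.
- A 100 Hz tone is rejected by ~38 dB, not infinitely; spectral leakage
  from strong low-frequency content can still reach the 300 Hz shoulder.
- The Mel filter bank follows the common audio convention; the sensor's
  original filter construction (pre-emphasis, lifter, normalization) is
  not public and may differ in detail.
- Accuracy grids on synthetic corpora are not predictions of field
  performance; only their ordering structure is designed to be
  meaningful.
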