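# Methods

This note records the models, numerical choices and limitations behind
each stage of the pipeline, and what the synthetic study can and cannot
show about real recordings.

## Speckle simulation

**Model.** The detected pattern is fully developed, polarized secondary
speckle: the field on the detector is the far-field (discrete Fourier)
transform of a circular pupil carrying i.i.d. uniform phases on
[0, 2π) — the phase screen standing in for skin roughness. Intensity is
the squared magnitude of that field, so its single-point statistics are
negative-exponential with unit contrast (σ/μ = 1), which the test suite
verifies by a Kolmogorov–Smirnov test over a full 224² frame.

**Translation.** Surface tilt θ maps to a rigid pattern translation
g·θ on the detector (g in px/µrad). Translation is applied in the
transform domain: multiplying the intensity spectrum by a linear phase
ramp shifts the band-limited periodic pattern *exactly*, including
subpixel amounts. For this to hold the intensity spectrum (the pupil
autocorrelation) must stay strictly below the Nyquist frequency, which
is why the default pupil diameter is 0.48 of the frequency grid rather
than 0.5: at exactly 0.5 the Nyquist bins carry energy whose phase ramp
a real-valued FFT cannot represent, and shift composition breaks at the
1e-5 level. At 0.48 the mean speckle grain is ≈ 2.1 px, satisfying the
K ≥ 2 sampling requirement that also drives the focal-length formula
F = K·Δx·Z3·D/(Z2·λ). That grouping is adopted deliberately: the
far-field grain size λZ2/D magnified by F/Z3 must span K pixels of
pitch Δx, so F grows with D — the only physically consistent reading.

**Tilt signal.** Each (smell, region) condition has the signature
θ(t) = Σⱼ aⱼ sin(2π fⱼ t + φⱼ) + cardiac pulse train + white tilt
noise, scaled by a distance gain. Defaults: two sinusoidal components
per smell with distinct frequencies in 5–60 Hz (control 5/55, alcohol
12/34, marijuana 18/44, menthol 26/52, garlic 8/59 Hz), amplitudes
1.0/0.7 µrad scaled per region (amygdala 1.0, olfactory bulb 0.6,
hippocampus 0.35), a 2 Hz pulse train (sharpened half-wave sinusoid,
0.3 µrad) as the cardiac-like baseline, 0.2 µrad RMS tilt noise, and
distance gains 1.0 at 0.1 m and 0.4 at 1.0 m. The region ranking makes
the qualitative "amygdala strongest" scenario reproducible as a
synthetic condition — it is an assumption of the generator, not a
biological finding. Tilt-to-shift gain defaults to 0.5 px/µrad.

**Sensor.** 8-bit quantization with the mean intensity at 20% of full
scale, additive Gaussian read noise of 2 DN, optional Poisson shot
noise. A float path (`bit_depth=None`, noiseless, unit mean) exists for
validating the speckle statistics without quantization artifacts.

**Protocol and seeding.** The default protocol is 5 s × 200 FPS × 4
repeats at 224×224 (4000 frames per video; the acquisition narrative
the protocol mirrors states 6000 frames for the same numbers, an
arithmetic inconsistency we expose as configuration rather than
resolve). Each repeat draws a fresh phase screen. Per-video seeds are
counter-based — `SeedSequence([master_seed, video_index])` — so any
single video regenerates bit-identically from its manifest row.

**Not modelled.** Speckle decorrelation ("boiling"), reflection-path
doubling, axial/longitudinal motion, fur and tissue scattering,
realistic hemodynamic waveforms, breed differences. Consequently,
passing tests show the *pipeline* recovers translation-encoded spectral
signatures at realistic SNR; they say nothing about whether real canine
brain regions produce class-separable vibrations.

## Displacement tracking

Zero-mean normalized cross-correlation computed via FFT (cyclic).
The integer peak is refined per axis by a 3-point parabola fitted on
the *logarithm* of the correlation samples when all three are positive
(a Gaussian peak model), falling back to a plain parabola otherwise.
The log fit reduces the worst-case subpixel bias from ≈ 0.05 px to
≈ 0.015 px on 2-px speckle, which matters once sequential tracking
accumulates hundreds of steps. Sequential mode (default) registers
consecutive frames and integrates; anchored mode registers everything
against frame 0. No drift correction is applied beyond optional mean
removal in the spectral step. Spectra are one-sided magnitude FFTs with
a Hann window by default (rectangular available for exact-tone checks).

## Features

Traces are cut into non-overlapping 40-frame windows that never span
two videos; differential channels are first differences *within* the
window, so chunks are self-contained. Per channel: mean, std, RMS, min,
max, range, energy, dominant frequency, spectral centroid, and band
powers over 0–10, 10–30, 30–60, 60–100 Hz (13 × 4 = 52 features, fixed
order, schema-hashed). Spectral features use mean-removed Hann-windowed
windows; at 40 samples and 200 FPS the resolution is 5 Hz — a
deliberate limitation documented here rather than hidden by zero
padding. The feature list is a fixed, reproducible schema chosen in
place of an open-ended feature-library catalogue.

## Gradient-boosted trees

Second-order boosting on the regularized objective: per round and class
a regression tree is grown on the softmax gradients g = p − 1{y=c},
h = p(1−p). Split search is exact greedy over all (feature, midpoint)
candidates scored by the structure-score gain
½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − G²/(H+λ)] − γ, with children required
to hold at least `min_child_hessian` (1e-3) of summed Hessian. Ties
break toward the lowest feature index, then the lowest threshold, so
training is invariant to row permutation. Leaves store the analytic
weight −G/(H+λ) together with (G, H) for auditing; predictions apply
shrinkage η. No subsampling, binning or missing-value routing — exact
greedy keeps the implementation equivalent to brute-force enumeration,
which the tests exploit. Defaults: η 0.1, depth 4, λ 1, γ 0, 100
rounds (the desk-scale studies use 25–40 rounds at depth 3 for speed).
The training log records log-loss and the full regularized objective
per round; on the tested fixtures the objective is non-increasing.

## Hyperparameter search

TPE-style: 10 random startup trials, then the history is split at the
25% quantile into good/bad sets; each parameter gets 1-D Gaussian KDEs
(Scott bandwidth, floored at 10% of the unit-scaled domain) augmented
with one wide prior kernel; 24 joint candidates are drawn from the good
mixtures (the prior kernel supplies a persistent exploration fraction)
and the candidate maximizing the summed log density ratio is evaluated.
The bandwidth floor is load-bearing: narrower kernels let the sampler
collapse onto near-duplicate incumbents and stall. Parameters are
modelled independently — this is "TPE-style", not a clone of any
framework. Integer domains are sampled continuously and rounded.
Failed (non-finite) trials are excluded from the densities. The
pipeline objective is validation macro-F1, maximized.

## Evaluation

Confusion matrices with rows as true classes; the normalized form
rescales each nonzero row to sum to 1.00 (all-zero rows are flagged,
not divided). One-vs-rest counts feed accuracy (TP+TN)/n, precision
TP/(TP+FP), sensitivity TP/(TP+FN), specificity TN/(FP+TN) and F1.
A zero denominator flags the metric *undefined* instead of coercing to
0, which would silently inflate macro averages for absent classes.
Multi-class summaries are unweighted (macro) means over defined
per-class values — chosen as the aggregation for single-number
summaries since no weighting scheme is canonical here; reports round to
2 decimals while CSVs keep full precision.

## Splitting and orchestration

The unit of assignment is the video tag: chunks inherit their video's
partition, so no chunk-level leakage is possible (verified by a test
that corrupts held-out features and checks the trained model is
unchanged). Within each dog, videos are shuffled per smell class and
round-robin interleaved across classes before the cumulative cut with
largest-remainder rounding — per-dog partition sizes are exact (8/2 for
10 videos at 80/20) *and* every contiguous cut stays representative of
the classes. Default split is 80/20 train/validation; a 70/15/15
three-way split is used when a separate test partition is requested —
the protocol being mirrored quantifies only the 80/20 division, so the
three-way fractions are this package's choice. Models are trained per
(region, distance) cell with dogs pooled, optionally per dog; the
control class is included in aggregated cells and excluded per dog by
default, both toggleable.

## Desk-scale study conditions

Full-physics simulation at protocol scale (360 videos × 4000 frames of
224² pixels) is unnecessarily large for validating the pipeline, so the
standard study in `analysis/`, the test suite and the reproduction
script runs a reduced design chosen once: 128 px frames on a 256 px
field, 1 s single-repeat videos at 200 FPS, 2 dogs, the high-amplitude
amygdala cell, both distances, 5 videos per cell (100 videos, 500
chunks). The SNR sweep uses 3 videos per cell at 0.8 s across signal
amplitude scales 0.08 / 0.3 / 1.0 with 5 seeds per level. All physics,
features and training parameters are unchanged from the full-scale
defaults except tree count (25–40 rounds, depth 3).

## Known limitations

* The simulator's class separability is injected; accuracy numbers
  characterize pipeline correctness, not real-world performance.
* Sequential tracking accumulates a slow random walk on noisy video;
  only mean removal is offered, no drift model.
* 5 Hz spectral resolution per chunk blurs components closer than one
  bin; the default signatures are chosen to be resolvable.
* The TPE sampler models parameters independently and will be
  inefficient on strongly correlated search spaces.
* Undefined macro metrics are skipped with a warning count; with very
  small validation cells this can average over fewer than C classes.
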