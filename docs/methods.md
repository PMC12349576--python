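# Methods

This note documents the models, protocols and numerical choices behind
`ssvepnet`: what is computed, under which assumptions, and where the design
was genuinely open.

## Synthetic SSVEP generator

### Signal model

A trial of class k (stimulus frequency f_k) on channel c is

    x_c(t) = g · γ_c · Σ_{h=1..H, h·f_k ≤ 50 Hz}  a₁ ρ^{h−1} sin(2π h f_k t + φ_{k,h,c})  +  n_c(t)

* **Harmonic series.** H = 4 harmonics with geometric amplitude decay
  ρ = 0.5 (fundamental amplitude a₁ = 1).  Harmonics above 50 Hz are
  omitted, matching the preprocessing band limit: real recordings carry
  little usable SSVEP power there.
* **Phases.** φ_{k,h,c} = β_{k,h} + 2π h f_k τ_c.  The base phase β_{k,h}
  is drawn once per subject — SSVEP responses are locked to stimulus onset,
  which is exactly why averaging training trials yields usable templates.
  τ_c ~ N(0, 15 ms) is a per-channel propagation latency, the mechanism by
  which real multichannel recordings span both quadratures of each
  harmonic.  A common per-trial latency jitter (sd 0.2 rad) models
  trial-to-trial response variability.
* **Spatial pattern.** Channel gains γ_c ~ U[0.5, 1] per subject with ±10%
  per-trial jitter: a stable but subject-specific topography.
* **Subject gain.** g = exp(N(0, 0.2)) per subject multiplies the signal
  only, so the cohort shows subject-level SNR variation around the nominal
  level, as human cohorts do.

### Noise and SNR

`snr_db` is the per-channel signal-to-noise power ratio defined on the full
band at 1000 Hz **before** any filtering — unambiguous and independent of
the downstream pipeline.  The noise sd per channel is set from the nominal
(g = 1) signal power, so the subject gain shifts each subject's realized
SNR by 20·log₁₀(g).  Two backgrounds are available:

* **white** (default): i.i.d. Gaussian.  Analytically convenient, and the
  SNR calibration is exact in expectation (tests verify ±0.5 dB from the
  stored signal/noise components over 100 trials).
* **pink**: white noise shaped by a first-order autoregressive filter
  (pole 0.95 at 1000 Hz, ≈8 Hz corner), renormalized to the same total
  power.  This mimics the low-frequency-dominated spectrum of resting EEG.

When a₁ = 0 the SNR rule cannot set a scale; `noise_sd` (default 1) is used
instead.

### What the generator does and does not emulate

It reproduces the *statistical skeleton* of a four-class SSVEP session:
stimulus-locked harmonic responses, stable per-subject topography and
phase, balanced randomized trials, 4 s stimulation (plus a 0.2 s rest tail
so sliding windows may legally extend slightly past stimulation), subject
SNR spread, and optionally a 1/f background.  It does **not** model volume
conduction, alpha rhythm, blinks/artifacts, non-sinusoidal VEP waveshape,
or spatially correlated noise.  Consequently, passing tests demonstrate
correctness and the *relative* behaviour of the methods under controlled
conditions — not human-level absolute accuracies.  Two regimes matter:

* Under **white noise** the harmonic templates of plain CCA are exactly the
  true signal subspace, making CCA matched-filter near-optimal (≈100% down
  to −10 dB).  This is a property of the linear-Gaussian model, not of real
  EEG.
* Under the **1/f background** at low SNR the picture reverses and matches
  the behaviour familiar from human recordings: harmonic-template CCA
  degrades sharply,
  subject-trained templates (CCA-M3) hold up better, and the trained
  network leads.  The method-ordering study therefore uses the pink
  background at −10 dB.

## Preprocessing

* **Downsampling** uses an order-8 Chebyshev-I anti-aliasing low-pass with
  zero-phase application before taking every 4th sample
  (`scipy.signal.decimate`); content below 50 Hz is preserved within the
  0.05 dB passband ripple.
* **Filter bank**: Butterworth bandpass designs of order 6 (12 poles per
  band) in second-order sections, bands (19–50), (14–38), (9–26),
  (3–14) Hz at 250 Hz.  Stability is asserted at design time (all poles
  strictly inside the unit circle).  Filtering is zero-phase
  (forward–backward) by default — phase handling on 0.256 s windows
  otherwise distorts the locked response; a causal single-pass mode exists
  for real-time fidelity.  The bank is applied to the cropped window (not
  the whole trial), accepting short-window edge effects in exchange for the
  pipeline ordering shown in the architecture diagram; filtering whole
  trials first is possible by harvesting windows from pre-filtered trials.
* **Random-initialization sliding window**: a window of P samples starts at
  `round((0.14 + r)·250)` with r ~ U[0, r_max].  By default r_max
  = 4 − d − 0.14 so crops stay inside the stimulation segment; setting
  r_max = 4 − d explicitly reproduces the literal augmentation range, which
  the 0.2 s synthetic rest tail supports.  Indices are 0-based, windows
  half-open.

## Network

Implemented from scratch in numpy (`ssvepnet.nn`): Conv2d via im2col,
BatchNorm2d (eps 1e-5, momentum 0.1, unbiased running variance), ELU,
inverted dropout, dense head, softmax cross-entropy, and Adam
(β = 0.9/0.999, eps 1e-8) with L2 weight decay added to the gradient for
weights (not biases or batch-norm parameters).  Initialization is the
fan-in-scaled uniform scheme, fully seeded.  All gradients are validated
against central finite differences in the test suite; eval-mode forwards
are bit-deterministic.

Architectural choices that were genuinely open:

* An ELU follows the stem's batch-norm, mirroring the residual blocks'
  activation; the stem has no dropout.
* "Dropout between layers" is read as dropout after each of layers 1–5 and
  none after layer 6.
* The main path is conv–BN–conv–BN with **no** activation between the two
  convolutions; ELU is applied only after the shortcut sum.
* With the default all-stride-2 plan the identity shortcut never triggers;
  it is implemented and unit-tested regardless (stride 1, equal channels).
* Window lengths that are not multiples of 64 build with a warning; the
  dense head is then sized by the shape trace (e.g. P = 100 → flatten
  length 128) rather than P.

## Training and evaluation protocol

Per subject: 100 training trials are split 9:1 class-stratified (largest-
remainder allocation so 100 → exactly 90/10); 20 random windows per trial
are harvested and filter-banked (90 trials × 20 = 1800, approximating the
protocol's nominal 2000 training windows with a round per-trial count); "iteration" means one mini-batch optimizer step
with batches drawn by reshuffled cyclic passes; validation accuracy is
measured every 50 iterations and the best-validation parameter state is
returned.  Test windows come from a held-out session of the same subject.

**Test-window policy.** All head-to-head method comparisons use
*onset-aligned* test crops (r = 0), the form the closed-loop application
consumes; training retains the random-crop augmentation.  CCA-M3 templates
are class means of onset-aligned crops — averaging randomly shifted crops
provably cancels the locked response (the well-known alignment difficulty
of trained-template CCA).

Metrics are computed from the 4×4 confusion matrix: accuracy
= trace/total, per-class one-vs-rest sensitivity TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP), F1 = 2·prec·sens/(prec+sens), all ×100;
the aggregate F1 is the macro average.  Degenerate denominators yield 0
rather than NaN.  Paired two-sided t-tests (scipy) compare per-subject
accuracies; zero-variance differences are rejected as undefined.

**Desk-scale defaults.** The bundled studies and the acceptance script
train 500 iterations at batch 64 per subject with cohorts of 2–10 virtual
subjects — sizes chosen so a full study runs in minutes on one CPU core
while leaving the protocol unchanged; the full-scale values (batch 250,
2000 iterations) remain the `TrainConfig` defaults.

## CCA solver

The first canonical correlation is solved in covariance form: Cholesky
factors of the auto-covariances whiten the cross-covariance and its largest
singular value is the correlation.  A ridge of 1e-8 (scaled by the average
variance) keeps rank-deficient inputs — all-zero windows, noiseless
harmonic signals — well defined, with a warning when rank deficiency is
detected; results are clipped to [0, 1].  The solver is cross-checked in
tests against brute-force numerical maximization of corr(aᵀX, bᵀY) and
against an independent iterative CCA implementation.  Classification
argmaxes the correlation over class templates with ties broken toward the
lowest class index.  Harmonic references use H = 4 with the hard 50 Hz
cutoff, matching the generator's harmonic content limit.

## Command mapping

Class k maps to the k-th listed object (listing order); the waypoint is the
object's (x, y) at the fixed 3 m cruise altitude.  Flight is constant-speed
straight-line kinematics with step min(speed·dt, remaining distance) —
the interface logic is the contribution here, not vehicle dynamics.  Legs
terminate within 1 mm; altitude is conserved exactly.

## Known limitations

* Absolute accuracies on synthetic data are optimistic relative to human
  EEG; only directional comparisons across methods transfer.
* The generator's SNR is defined pre-filtering on the full band; effective
  in-band SNR after the filter bank is substantially higher.
* The numpy network trains on CPU only; at full scale (2000 × 250) a run
  takes correspondingly longer than the desk-scale studies.
* Reading real MAT-file recordings is out of scope; the HDF5 container is
  the package's interchange format.
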