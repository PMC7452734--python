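# Methods

This note documents the models, parameter choices, and numerical
decisions behind `hydracal`, and what the synthetic validation does and
does not establish about real recordings.

## Signal model

A whole-body fluorescence recording is modeled as

    F(t) = B · e^(−t/τ_bleach) · (1 + ΔF/F(t) + ε(t)),

with baseline B (a.u.), photobleaching time constant τ_bleach, white
Gaussian sensor noise ε of SD `noise_sd` (in ΔF/F units, so the noise
level survives normalization unchanged), and

    ΔF/F(t) = Σ_i A_i · k(t − t_i),   k(t) = e^(−t/τ_d) − e^(−t/τ_r).

The kernel peaks at t\* = ln(τ_d/τ_r)·(1/τ_r − 1/τ_d)⁻¹ with value
k(t\*) ≈ 0.535 for the defaults τ_r = 0.3 s, τ_d = 1.5 s (GCaMP6s-like;
the indicator's published kinetics, not a fit). Kernels are placed so
the transient *peaks* at the event time t_i: ground truth and detector
output then live on the same clock, and detection error is measured
without a systematic kernel-delay offset.

Two event classes: CB pulses (amplitude 1.0 ΔF/F) arrive in bursts —
burst onsets are Poisson with rate `cb_burst_rate × osmolarity
multiplier`, each burst carrying 1 + Poisson(4) pulses spaced 2 s
apart; RP1 pulses (amplitude 0.4) are jittered-periodic (period
3600/`rp1_rate`, Gaussian jitter SD 10% of period). Burst onsets
closer than 30 s to the preceding burst's end are shifted to that
refractory boundary (preserving the Poisson count, unlike rejection);
RP1 pulses within 5 s of a burst window are discarded — the RP1
circuit fires during elongation, not around contractions. Muscle-like
recordings set `rp1_rate = 0`.

### Signal-to-noise convention

`SimulationConfig.snr` is the peak ΔF/F of the *weakest event class
present* divided by `noise_sd`. Detectability is limited by the
smallest transient the detector must find (RP1 in neural recordings),
so an "SNR 5" recording has RP1 peaks at 5 noise SDs and CB peaks at
12.5. `with_snr(s)` sets `noise_sd` accordingly; the default
`noise_sd = 0.02` corresponds to a clean recording (SNR ≈ 10.7),
reflecting that a mean over ~10⁴ animal pixels has little shot noise.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| duration, frame_rate | 7200 s, 2 Hz | the 2-h activity protocol (width movies: 0.5 Hz) |
| cb_burst_rate | 6 /h | control-condition burst rate (~one contraction burst per 10 min) |
| pulses_per_burst_mean | 4 | burst size 1 + Poisson(4), mean 5 |
| intra_burst_interval | 2 s | in-burst pulse spacing |
| min_interburst_interval | 30 s | refractory elongation phase |
| rp1_rate | 60 /h | ~1 elongation pulse per minute |
| cb/rp1 amplitude | 1.0 / 0.4 ΔF/F | amplitude is the usable secondary classification cue |
| condition multipliers | 1.5 / 1.0 / 0.5 | low / control / high osmolarity; synthetic, direction-matched, not measured |
| elongated/contracted width | 40 / 80 px (low 48, high 30) | body column widens and shortens on contraction |
| elongated/contracted length | 240 / 120 px | exact mirror of width |
| contraction/elongation τ | 2 s / 30 s | fast contraction, slow re-elongation |

No per-condition burst rates are published for this preparation; the
multipliers are placeholders that reproduce the *direction* of the
osmolarity effect and remain configurable.

## Normalization

ΔF/F uses a running low-percentile baseline: F₀ at each sample is the
10th percentile of a centred 120-s window, evaluated on a coarse grid
(stride ≈ window/8) and linearly interpolated. Windows truncated at
the trace ends would bias F₀ toward the local value, so the first and
last half-window are linearly extrapolated from the adjacent
full-window baseline instead. With τ_bleach = 1800 s this leaves a
residual baseline wobble of ~0.002 ΔF/F over 2 h (a constant offset of
~0.027 remains, which detection absorbs by referencing its height
threshold to the trace median). The percentile window (120 s) must sit
between the longest burst (~20 s) and the fastest bleaching it should
track.

## Pulse detection

The detector is deliberately fully automatic (the workflow it replaces
was semi-manual with unpublished internals); its knobs are artifact
choices, tuned on the generator:

baseline_window 120 s, threshold_k 4, min_separation 2 s,
prominence_window 30 s, max_ipi 10 s, min_pulses 2,
amplitude_ratio 0.7.

Noise is estimated as σ̂ = 1.4826·MAD(diff(x))/√2, immune to slow
signal. A single peak scan cannot serve both regimes present in these
traces, so two scans feed one candidate list:

* **Smoothed scan** — binomial kernel (¼, ½, ¼); thresholds scaled by
  the filter's noise gain √(Σw²) ≈ 0.61. Averaging buys the weak
  isolated RP1 pulses ~1.6× SNR; it destroys in-burst resolution, which
  the second scan restores.
* **Decay-whitened scan** — y_t = x_t − g·x_{t−1}, g = e^(−1/(τ_d f_s)).
  For transients with exponential decay τ_d this cancels the
  accumulated tail of all earlier pulses, so every in-burst pulse
  appears as a near-full-amplitude impulse; noise gain √(1+g²). This is
  the matched-filter assumption: the detector knows the indicator's
  decay scale (a knob, default 1.5 s).

Both scans require height ≥ median + k·σ_scan (the median reference
removes the percentile-baseline offset) and prominence ≥ k·σ_scan
within a 30-s window (localizing prominence, since over longer spans
deep valleys inflate the prominence of pure-noise peaks). Scan peaks
snap to the largest raw local maximum within ±2 samples. Candidates
merge amplitude-first with a minimum separation of
round(min_separation·f_s) − 1 samples — one sample of slack so that
true pulses spaced exactly 2.0 s survive grid round-off. Finally, when
two kept maxima lie within min_separation and the valley between them
is shallower than k/2 noise SDs, they are one transient, not two, and
the smaller is dropped (shared-valley suppression).

Reported per pulse: peak time, ΔF/F amplitude, raw prominence (clipped
to ≤ amplitude), and width at half prominence (the RP1 "total time"
unit, since no duration is otherwise defined for single pulses).

Classification: burst members are CB; isolated pulses are RP1 if their
amplitude is below 0.7× the median CB amplitude, otherwise single-pulse
CB events when min_pulses = 1 and flagged `unassigned` otherwise (with
no bursts at all, the largest pulse anchors the CB scale). Ectoderm and
endoderm (muscle) recordings force every pulse to CB candidacy — RP1
is a neural signal absent from muscle activity.

CB pulse frequency is defined as intra-burst frequency (CB pulses per
minute of total burst time) and reported 0 when no burst exists.

## Width morphometry

Frames are segmented by Otsu threshold, keeping the largest connected
component with holes filled. The moment-equivalent ellipse (axes =
4√eigenvalues of the coordinate covariance) summarizes the mask; the
minor axis is the body-column width — the only ellipse scalar that
matches "width of the body column". On rendered ellipses with axes
20–200 px across all orientations the minor-axis error stays ≤ ~1%
(discretization), within the 1.5% budget. Isolated invalid frames are
linearly interpolated; runs of invalid frames stay invalid, and more
than 20% invalid frames is an error. Units are pixels, or µm when a
pixel size is supplied.

Cycle minima (end-of-elongation widths) are prominence-filtered local
minima (default 5% of the trace range, min period 60 s). Note that on
long inter-contraction intervals the width sits on a flat plateau near
its floor: the *time* of the measured minimum is then noise-determined
while its *width* is stable — validation therefore matches minima per
inter-contraction interval and scores widths (≤ 0.6% error observed),
not plateau timestamps. The contraction counter flags excursions where
body length drops below (1 − 0.3)× its preceding local maximum and
recovers — an automated surrogate for manual scoring.

## Statistics

Mean ± SEM (n−1 SD). Two-tailed unpaired pooled-variance Student's t
(the named test of the workflow being reproduced — not Welch); with
zero pooled variance, p = 1 for equal means and p = 0 otherwise, by
documented convention. One-way fixed-effects ANOVA; Tukey HSD with the
Tukey–Kramer SE √(MS_within/2·(1/nᵢ+1/nⱼ)) for unequal n. p-values and
simultaneous 95% CIs both come from the same studentized-range
distribution, so `significant`, p < 0.05, and 0 ∉ CI necessarily agree.

The studentized-range CDF is evaluated in-package by fixed
Gauss–Legendre quadrature of

    F(q; k, ν) = ∫ f_{χ_ν/√ν}(s) · R_k(qs) ds,
    R_k(x) = k ∫ φ(z)[Φ(z) − Φ(z − x)]^{k−1} dz

(128 z-nodes on ±9, 96 s-nodes over ±12 SDs of the scaled-χ), accurate
to ~1e-5 against adaptive-quadrature references and ~3 orders of
magnitude faster — fast enough to run 10⁴-replicate null calibrations
in seconds. Tests cross-check it against `scipy.stats
.studentized_range` and `scipy.stats.tukey_hsd`. Critical values are
cached per (α, k, ν).

Report tables carry one row per pairwise comparison with columns
Figure/Description/Method/CI_low/CI_high/Significant/p; three-level
factors get Tukey rows ordered control-vs-low, control-vs-high,
low-vs-high, two-level factors a single t row. No correction is applied
across metrics.

## Validation design and problem sizes

All validation is against the generator's ground truth, at these sizes
(chosen to make each estimate's own Monte-Carlo error small relative to
its acceptance margin):

* Detection: 100 recordings of 2 h at 2 Hz, SNR 5; pulse matching by
  greedy nearest-first 1:1 pairing within ±1 s (ties to the earlier
  detection; empty-detection precision defined as 1). Observed: F1
  ≈ 0.98 on every seed; burst count within ±1 on ≥96/100.
* Classification: ~5000 matched pulses over 30 recordings; ≈99%
  accuracy. Residual errors are mostly RP1 pulses arriving within
  max_ipi of a burst edge, which IPI grouping necessarily absorbs.
* Width: 63-case axis/orientation sweep plus a rendered 2400-s movie.
* Statistics: the t test is compared with a 10⁵-draw permutation
  oracle on small-n cases; agreement is bounded by the systematic
  exact-vs-asymptotic gap at n = 6–10 (up to ~0.04), not by
  Monte-Carlo error, so the tolerance is 0.05. Tukey's family-wise
  error under the null is calibrated with 10⁴ simulated 3×8
  experiments (observed ≈ 0.049).
* Headline effect: 100 replicate experiments (3 conditions × 8
  recordings × 2 h). The full 2-h protocol is used because, at the
  realistic 6 bursts/h control rate, 10-min recordings contain too few
  bursts (~1 per recording) for group ordering to be stable at n = 8 —
  with 2-h recordings the low > control > high CB ordering and the
  low-vs-high Tukey significance are recovered in ~100% of replicates.
  The per-recording simulate-and-detect chain costs ~25 ms, so the
  full-scale validation runs in about a minute.

## What the synthetic validation does not show

The generator emulates the *statistical structure* the analysis
assumes: Poisson bursts, quasi-periodic RP1, difference-of-exponential
transients, white noise, exponential bleaching, a rigid ellipse body.
Real recordings add motion of a deforming animal, non-white and
signal-dependent noise, focus drift, tentacle and bud geometry, and
overlapping behaviors — none of which are modeled. Passing tests
demonstrate correctness of the implementation under its stated model
and adequate power of the experimental design, not performance on any
particular real dataset. Published numeric endpoints of the original
width and activity experiments derive from unreleased recordings and
are deliberately not targets; only directions and procedures are
reproduced.

## Degenerate inputs and tie-breaking

Noiseless traces (σ̂ = 0) use a floor of 1e-12 so thresholds reduce to
"any positive local maximum". Bursts with a single true pulse are
invisible to a min_pulses = 2 detector by design and are excluded from
exact burst-recovery comparisons (they remain within the ±1 tolerance
otherwise). Equal-amplitude candidates in the dedup are resolved
earliest-first; plateau maxima take the leftmost sample. Empty cycle
sets report their mean width as NaN, never 0.
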