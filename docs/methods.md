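# Methods

This note documents the models behind `cardioep`: what the synthetic
generators emulate, how each analysis stage works, the tunable parameters
with their defaults and units, the numerical choices made where the design
was genuinely open, and what the passing tests do and do not demonstrate
about real recordings.

## Study conditions

The package targets the rat aorto-caval-fistula (ACF) volume-overload
model: cohorts of sham-operated controls and shunted animals stratified by
heart-to-body-weight ratio (HBWR, heart = both ventricles + septum, g/kg)
into mild, moderate and severe groups with sizes (10, 5, 8, 4). Generator
defaults are the published group means: e.g. sham ECG at 414 bpm with
P 15 ms, PR 47 ms, QRS 18 ms, QT 78 ms; sham conduction velocities
102/14.6 cm/s (longitudinal/transverse) and APD50/APD90 of 56/94 ms; mild
CVs of 184/32 cm/s. Acquisition geometry follows the study: 1 kHz ECG
sampling; movies at 500 frames/s, 80 μm pixels, an 8×8 mm field, and 300 ms
pacing from the field center.

## Synthetic ECG

Each beat is a sum of three components placed relative to the QRS onset so
the requested intervals hold exactly in the noise-free limit:

* **P and T waves** — Gaussians truncated at ±2σ with σ = duration/4,
  shifted so they reach exactly zero at the window edges and rescaled to the
  requested peak amplitude. Truncation makes onset and end analytic; the
  σ = duration/4 shape keeps the P upstroke close enough to linear that the
  least-squares-line onset rule lands within half a sample of the truth.
* **QRS** — piecewise linear through (0, 0) → (0.15 d, Q) → (0.40 d, R) →
  (0.75 d, S) → (d, 0) for QRS duration d. The triphasic deviations are
  apportioned (10.4 / 72.5 / 17.1)% of the requested |Q|+|R|+|S| sum. The
  linear segments give a constant intra-QRS |dV/dt| well above the
  delineator's 10% threshold and exactly zero slope outside.
* The ST segment occupies the first quarter of the QRS-offset→QT span; the
  T wave the remainder.

RR intervals are lognormally jittered (default SD 2% of the mean — keeps RR
positive); beats are emitted only if fully contained in the recording, with
the first QRS onset at PR + 10 ms. Additive white noise; the truth channel
lists every beat's fiducial times and the isoelectric level.

A beat whose PR + QT extent exceeds ~95% of the mean RR is rejected as
overlapping. Parameter sets with PR < P duration or QT < QRS are invalid.

## ECG analysis

* **Detection** — threshold crossings (half the 99th percentile of the
  magnitude) of a 5–90 Hz zero-phase band-passed trace, 50 ms refractory
  lockout, each R refined to the most positive raw sample within ±25 ms.
* **Classification** — a median-beat template over the averaging window;
  good iff correlation ≥ 0.9 *and* both adjacent RRs within ±20% of the
  running-median RR (window 11). Fewer than 3 beats ⇒ all bad.
* **Averaging** — first 200 consecutive good beats (or all available, with
  a warning), windowed 80 ms pre / 120 ms post R and averaged sample-wise.
  The 80 ms pre-window (rather than a tighter 60 ms) is needed because at
  severe-group PR ≈ 58 ms the P onset would otherwise fall outside the
  window; 80+120 ms still sits inside one RR at rat heart rates ≤ 480 bpm
  only marginally, and neighbor-beat bleed-in is tolerated because every
  delineation search below is bounded.
* **Delineation** — QRS bounds: scanning outward from R, the first sample
  where |dV/dt| (forward difference) stays below 10% of the intra-QRS
  maximum for ≥ 3 consecutive samples (both fractions configurable).
  Isoelectric level: median of everything before the onset; the noise SD is
  a MAD estimate on the same window (robust to the P wave occupying a
  minority of it). P peak: greatest |deviation| before the QRS onset;
  P onset: isoelectric-line intersection of a least-squares line through
  the points 15–60% of the provisional onset-to-peak span before the peak;
  P end (needed for P duration, which the interval set defines separately
  from PR): first return into the isoelectric band after the peak, capped
  at QRS onset — deliberately symmetric with the T-end rule. T peak: first
  extremum after the QRS offset (located on a 3 ms moving-average smoothed
  trace, measured on the raw trace) deviating ≥ 2 noise SDs; T end: first
  subsequent sample back inside that band. Every absent fiducial carries a
  reason code, and measures depending on it are NaN.
* **Measures** — PR = P onset→QRS onset; QT = QRS onset→T end; QTc by the
  classical Bazett form QT/√RR with RR in seconds (no rodent-specific
  re-normalization; flagged, since species-adapted exponents exist);
  QRS sum = |Q|+|R|+|S| relative to the isoelectric level; ST height
  measured 15 ms after the alignment point.

## Synthetic optical-mapping movies

The truth activation time is analytic: with pixel offsets rotated into the
fiber frame (a along, b across, in cm), t = first_stim +
√((a/CV_long)² + (b/CV_trans)²), i.e. elliptical isochrones. The
action-potential template is a linear upstroke of 4 ms (two frame intervals
at 500 fps) centered on the truth activation time, followed by a monotone
PCHIP repolarization pinned to (APD50, 50%) and (APD90, 10%) of amplitude,
reaching zero at APD90 + (APD90 − APD50)/2. Two design points matter:

* The upstroke is a **two-frame ramp, not a one-frame step**. A sampled
  step carries no sub-frame information — every activation time would be
  quantized to the 2 ms frame grid, which is far too coarse for rat
  longitudinal CV over an 8 mm field (the fitting annulus is crossed in
  ~2.5 ms). A ramp spanning exactly two frame intervals makes the
  three-point parabolic interpolation of the derivative maximum recover the
  activation phase *exactly* in the noise-free limit.
* The derivative maximum of the template sits at the truth activation
  time itself (ramp centered on t = 0), so detection convention and truth
  agree without offset bookkeeping.

Pixels under an optional block mask carry baseline + noise only; the wave
does not detour around the block (no electrotonic coupling — the generator
is kinematic, not reaction–diffusion). Depolarization is a signal increase
(polarity +1); recordings with dye-type negative polarity are flagged and
flipped during preprocessing. A configuration whose slowest pixel would
activate after the last frame is rejected, naming the pixel.

## Optical-mapping analysis

* **Preprocessing** — polarity normalization, optional zero-phase temporal
  band-pass (Butterworth order 4; default corners 0.5–100 Hz when enabled),
  then a per-frame 3×3 spatial median filter with reflect padding. The
  *default analysis chain does not apply the temporal band-pass*: at
  500 fps the 100 Hz low-pass smears the upstroke over several frames and
  degrades sub-frame timing (measured fast-axis CV bias up to ~8–14%),
  while the 0.5 Hz high-pass sags the AP plateau and biases APD50 by
  ~10 ms. The band-pass exists for drifting, lamp-flicker-contaminated real
  signals; on such data, CV and APD tolerances quoted below do not apply.
* **Activation** — within one pacing cycle (the window opens two frames
  before the stimulus so early upstrokes keep their left derivative
  neighbor, and closes two frames before the next stimulus so its upstroke
  cannot be captured), activation is the time of the maximal forward
  difference, refined by a parabolic fit over the three surrounding
  derivative samples (clipped to ±half a frame). A pixel is invalid ("low
  SNR") when its upstroke amplitude is below 4× its pre-stimulus noise SD
  or below 10% of the median upstroke amplitude; the second clause
  invalidates silent pixels even in noise-free data.
* **Isochrones** — integer bands floor(t / 2 ms); boundary polylines are
  extracted as sub-pixel contours for plotting.
* **APD** — per ROI, valid pixel traces are aligned on their integer
  activation frame and averaged; the mean sub-frame remainder is carried so
  APD is referenced to the true mean activation. Amplitude = peak −
  pre-upstroke baseline; APD_x is the time to the last crossing of
  baseline + (1 − x/100)·amplitude before the next stimulus, linearly
  interpolated between frames. A fall of > 40% of amplitude between
  adjacent frames is treated as an under-resolved instantaneous edge and
  every crossing inside it is assigned the segment midpoint: this makes
  square-pulse APD50 = APD90 = pulse width exact while never triggering on
  physiological repolarization rates. The ROI value is that of the averaged
  trace (not the mean of per-pixel APDs) — less noise-sensitive.
* **Conduction velocity** — for θ in 0…175° (5° steps), valid pixels within
  ±2.5° of the line {θ, θ+180°} and inside a 0.4–3 mm annulus around the
  pacing site are regressed: activation time on radial distance; the
  directional speed is 1000/slope (cm/s). The fit uses *unsigned* radial
  distance pooled over both rays: for a central point source activation is
  symmetric, so a signed-distance fit would always return slope ≈ 0. The
  0.4 mm inner radius excludes the stimulus-electrode region. CV_max is the
  fastest direction (its angle refined below the scan step by a parabolic
  fit of 1/v², which is sinusoidal in 2θ for elliptical spread); CV_min is
  taken in the direction orthogonal to CV_max — the long-axis/short-axis
  convention — rather than the free global minimum. Anisotropy =
  CV_max/CV_min ≥ 1. Directions whose fitted slope implies a speed above
  2000 cm/s (including flat fields) are skipped as non-physiological;
  fewer than 10 valid annulus pixels or no usable direction raises an
  "insufficient coverage" error.
* **Block** — connected components (8-neighborhood) of pixels that are
  invalid or activate > 10 ms after all their valid 4-neighbors, with area
  ≥ 10 pixels; reported with area and bounding box. Because the 3×3 median
  filter bleeds signal into the one-pixel rim of a silent region, a block
  component recovers the truth mask minus (part of) its rim — about 93% of
  a 15×15 mask.

Known quantization bounds: noise-free activation error is < half a frame
everywhere; recovered CVs sit within ~2% of truth (wedge-width averaging of
the elliptical speed profile accounts for most of it) and within ~10% at
20 dB SNR; APDs within ~1 ms of the template anchors.

## Densitometry

Lane profiles are 1-D (per-band quantification; 2-D gel extraction is out
of scope). Background under a band window is a least-squares line through
two flanking margins of 10% of the window width each; subtraction is exact
for any affine baseline with clean flanks. Integrated density is clipped at
zero with a warning. Expression = target/loading-control ratio, optionally
rescaled so the reference (sham) group mean is 1.

## Cohort generation and statistics

Cohort tables draw each variable per group from a normal distribution; a
single latent severity factor z per animal imposes cross-variable
correlations (corr(u, v) = λ_u λ_v, loadings solved by least squares from
the requested pairs; an inconsistent request — one not representable by a
single factor, equivalently a non-PSD target matrix — is rejected). Weight
identities are preserved by construction: heart weight is the sum of the
drawn LV/septum/RV components and HBWR is derived, not drawn. Protein
densities default to a monotone sham→severe decline mirroring the reported
connexin43 and innervation-marker trends, with connexin43 negatively loaded
on the severity factor.

Severity cuts default to the midpoints of the gaps between the published
per-group HBWR ranges (4.88→5.19 and 5.73→5.99 g/kg ⇒ cuts 5.035 and
5.86), so any cohort drawn inside those ranges is partitioned identically.
The failing/non-failing split is lungs/BW ≥ 5 g/kg; the boundary itself
counts as failing (the verbal "below/over 5" leaves 5.0 exactly ambiguous —
the convention is documented here and configurable).

Group summaries report mean ± SD (not SEM) and per-cell n with pairwise
deletion of missing values. ANOVA is the standard one-way F test. Dunnett
many-to-one adjusted p-values are computed from the equicoordinate box
probability of the multivariate t distribution of the maximum |statistic|
(pooled variance; correlation √(n_i n_j/((n_i+n₀)(n_j+n₀))); numerical
integration with a fixed QMC seed, so results are deterministic); the
single-treatment case reduces exactly to the pooled two-sample t-test, and
adjusted p is floored at the unadjusted p. Tests are two-sided. Pearson r
uses the product-moment formula with the two-sided t transform on n − 2 df.

The anisotropy convention deserves a note: the source material verbally
defines anisotropy as transverse/longitudinal, yet its tabulated values
(~7) can only be longitudinal/transverse. The package reports
CV_max/CV_min ≥ 1 and documents the discrepancy rather than silently
following the text.

## What the synthetic tests do and do not show

The generators share the analytic forms that make ground truth exact:
noise is white, baselines are flat, wavefronts are exactly elliptical, AP
upstrokes are exactly two frames, and beats within a recording differ only
by sampling phase and noise. Passing recovery tests therefore demonstrate
the *correctness and calibration of the algorithms under the stated model*,
not robustness to motion artifact, baseline wander, fractionated
electrograms, wavefront curvature on a 3-D surface (flagged in the field as
inflating apparent transverse slowing), or repolarization heterogeneity.
Repolarization-dispersion mapping, phase/rotor analysis, and
reaction–diffusion simulation are explicitly out of scope.

## Problem sizes used in the shipped checks

The shipped verification runs use 50 recordings for interval recovery
(10–30 s each at 1 kHz), 100×100×160-frame movies for CV/APD/block
recovery, 10,000 replicates for Dunnett family-wise-error calibration
(vectorized against the one-time equicoordinate critical value), 200 seeds
for the ANOVA significance pattern and 500 for the correlation recovery,
and the full 27-animal pipeline for determinism — sizes chosen so each
check is statistically informative while the whole suite stays interactive.
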