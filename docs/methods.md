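# Methods

## The synthetic trial model

The generator (`depthgait.synth`) emulates the data streams of a
water-depth-gradient locomotion experiment on an elongate amphibious fish. It
is a minimal model chosen to reproduce the *measured variables* of such a
study, not the fluid or contact mechanics.

**Body.** The midline is an inextensible curve of length BL parameterized by
arc length `s ∈ [0, 1]` (nose = 0, tail = 1) carrying a lateral traveling
wave

    y(s, t) = BL · A(s) · sin(2π(f·t − s/λ)),

with wave frequency `f` (default 2 cycles/s), wavelength `λ` (default 1 BL)
and an amplitude envelope `A(s)` in BL (default `0.01 + 0.07·s²`, the usual
head-to-tail amplitude growth of an undulatory swimmer; swimming-range
magnitudes of a few percent BL). The longitudinal coordinate integrates
`dx = √(ds² − dy²)`, so arc length is conserved exactly: the 100 output points
are equally spaced in arc length by construction and the nose–tail chord never
exceeds BL — the geometric premise of the curvature coefficient. The whole
body translates at a constant forward speed (default 1 BL/s). Envelopes steep
enough to violate `|dy/ds| < 1` are rejected at validation.

**Pectoral fins.** The fin-lobe tip is placed by rotating the skull→nose ray
by the fin angle `θ(t) = 90° + 30°·cos(2πf_fin·t)` (default 1.5 cycles/s,
range of motion 60°), so the measured nose–skull–fin angle equals the
generative angle exactly on clean data. The left fin's adduction phase within
each right-fin cycle is drawn per cycle from a von Mises distribution with
mean `fin_phase_offset` (0° = in-phase, 180° = out-of-phase) and concentration
`fin_phase_kappa`; `κ = ∞` means exact phasing, and a mixed mode alternates
0°/180° to emulate trials containing both coordination patterns. The left-fin
angle series is reconstructed from a monotone piecewise-linear cycle-phase
function through those per-cycle adduction times, so ground-truth event times
are exact.

**Nose elevation.** One lift per fin cycle, `z(t) = amp·(1 − cos(2πf_fin·t))/2`
(default amplitude 0.1 BL), peaking at fin-cycle midpoint (180°).

**EMG.** Channels are zero-mean Gaussian noise whose standard deviation is a
constant baseline (0.05) plus `gain × Hann envelope` inside each burst. Bursts
occupy `burst_duty` (default 0.4) of the tailbeat cycle; onsets advance by
`onset_lag_per_site` (default 30° of cycle) from anterior to posterior
electrode sites and are shifted 180° on the contralateral side — a
swimming-like anterior-to-posterior, left/right-alternating activation wave.
The Hann/baseline construction makes the top-5% "theoretical maximum"
normalization analytically approximable and gain-invariance testable.
Electrode layout defaults to five left-side axial positions (19.8, 33.1, 42.8,
57.4, 67.4 %BL) plus right-side electrodes at positions 2 and 4.

**Landmark noise.** Optional i.i.d. Gaussian jitter (in BL) on every landmark
and midline coordinate models digitizing error.

**Depth mapping.** `generate_depth_sweep` varies three things with water depth
(BD), all as explicit configuration (`DepthMapping`), never hard-coded: the
amplitude envelope scales up below a reference depth (slope 0.6 per BD),
anterior-site burst gain rises (slope 1.5 per BD below reference, sites
< 40 %BL), and the fin phase offset switches 0° → 180° below a threshold
depth (default 0.8 BD). Real per-depth envelope shapes are unreported for
this kind of study; this mapping is a documented stand-in that reproduces the
qualitative patterns (rising body curvature and anterior muscle effort, a
discrete fin-coordination switch), which is exactly what the property tests
assert — nothing quantitative about real fish follows from them.

**What the generator does not emulate:** ground-reaction and fluid forces,
speed–frequency covariation, inter-individual variation, electrode
cross-talk, movement artifacts, or non-stationary baselines. Passing tests
show the *estimators* are correct and calibrated, not that real data are this
clean.

## Estimators and numerical choices

* **Travel axis** — first principal component of the nose trajectory,
  oriented along net displacement; lateral displacement is the perpendicular
  component, left positive, in BL. Over a multi-BL track the estimated axis
  can tilt by ~0.1% BL, which bounds the accuracy of small lateral
  amplitudes.
* **Low-pass filtering** — all digitized series are filtered zero-phase
  (4th-order Butterworth) before extremum or path-length operations: default
  corner 10 Hz at 500 frames/s, 6 Hz for fin angle (~4× the fin-beat
  frequency), 5 Hz for nose height. Path length and per-cycle extremes are
  otherwise biased upward without bound by frame-to-frame jitter.
* **Extremum detection** — local extrema of a 5-frame moving average with
  minimum prominence 10% of the signal range; runs of same-sign extrema keep
  the most extreme member; extremum pairs whose excursion is below 50% of the
  median excursion are pruned as jitter/edge artifacts.
* **Stroke phase** — both stroke clocks anchor 0° and 180° to named events
  (right-fin adduction/abduction starts; tail swing right/left starts), so
  phase is mapped piecewise-linearly over the two half-cycles rather than by
  a single linear map, which could not honor both anchors for asymmetric
  half-cycles.
* **Nose elevation baseline** — a low percentile (default 1%) of the filtered
  nose height rather than the raw trial minimum: the substrate height is not
  separately recorded, and the raw minimum is biased low by jitter.
* **EMG conditioning** — zero-phase 60 Hz notch (Q = 30) then zero-phase
  40–4000 Hz band-pass; the high corner is clipped just below Nyquist with a
  warning when the sampling rate is too low. Zero-phase filtering avoids
  onset-time bias.
* **Burst detection** — hysteresis on a 10 ms moving-average rectified
  envelope: detection at baseline + 3 SD, edges extended to baseline + 0.5 SD
  and then refined by extrapolating the local envelope slope back to baseline
  (bounded at 12 ms). The extrapolation counters the systematic lateness of
  threshold crossings on gradually rising bursts. Gaps < 25 ms are merged and
  bursts < 20 ms dropped. Manual annotation tables override detection.
* **RIA** — `100 · Σ|v| / (max_rate · n)` with `max_rate` the mean of the top
  5% of *conditioned, rectified* amplitudes pooled per electrode within each
  fish (pooling scope configurable per trial vs per fish; per fish is the
  default). Sample counts are the time base on both sides, so gain and units
  cancel exactly.
* **Cycle attribution** — a burst belongs to the tailbeat cycle containing its
  onset; duty factors above 100% are allowed and flagged, as are offsets that
  wrap past the cycle boundary.
* **Hermans–Rasson test** — corrected pairwise O(n²) statistic (the variant
  with the 2.895·|sin| term); p-values by seeded Monte-Carlo simulation
  (default 9999 replicates, `(1 + exceedances)/(n_mc + 1)`), exact at any n
  and bit-reproducible.
* **von Mises check** — Watson U² against the ML-fitted von Mises with a
  parametric bootstrap null (default 200 replicates), since U² with estimated
  parameters is not distribution-free. κ is estimated by inverting
  `I₁/I₀ = R̄` (Fisher's starting value refined by root finding; asymptotic
  form `κ ≈ 1/(2(1−R̄))` for R̄ > 0.999, capped at 10⁸). Any calibrated GOF
  test would serve; this one is swappable.
* **Rayleigh test** — mean resultant length with the standard small-sample
  series correction for the p-value.
* **Classification order** — HR first; if non-uniform, the von Mises check
  gates Rayleigh; means and angular variances are reported only for
  non-uniform unimodal samples. A within-trial screening variant skips the HR
  step when only unimodal in-/out-of-phase behaviour is in question.
* **Watson–Williams** — standard F with the `1 + 3/(8κ̂)` correction; the
  common-concentration assumption is logged when the pooled within-group
  resultant falls below 0.45.
* **Degenerate inputs** — zero-resultant samples have no defined circular
  mean (error); constant signals yield no stroke events (error); coincident
  landmarks flag frames as missing rather than fabricating angles.

## Study pipeline defaults

The default `StudyConfig` analyses 4 s trials (≥ 5 tailbeat cycles, the
trial-inclusion filter, configurable) at the eight depth treatments 3.0, 2.0,
1.1, 1.0, 0.9, 0.7, 0.1, 0.0 BD with three trials per depth, 0.3% BL
digitizing jitter and fin-phase concentration κ = 20 (~13° SD) — scatter
comparable to real digitized stroke timing. Test and acceptance runs use
reduced designs (two to four depths, two trials each, 999 HR replicates, 100
bootstrap replicates) so the whole suite runs in well under a minute per
scenario on one CPU; the statistics are identical, only Monte-Carlo precision
differs. Trial means are the unit of analysis for linear variables; phase
samples pool cycles within depth. Linear mixed-effects fits are exported as a
tidy model-ready table rather than re-implemented — they are routine and
belong to dedicated mixed-model libraries.

## Known limitations

* `midline_from_mask` treats frames independently (no temporal smoothness
  constraint) and requires an explicit head hint; head/tail disambiguation
  from shape alone is out of scope.
* Skeleton paths shrink slightly at blunt body ends (skeletonization cannot
  reach the boundary), so mask-derived body length underestimates true length
  by up to a few percent of the body width.
* The Watson–Williams test assumes roughly equal, sufficiently large
  concentrations; it is applied as the study design prescribes, with the
  assumption check logged, not enforced.
* Speed uses net nose displacement, not path length; sinuous paths at fixed
  gait therefore read slower. This matches the conventional definition and is
  documented so users can switch.
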