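# Methods

This note records the models, conventions, numerical choices and known
limitations behind `capnoshape`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted from memory of external data.

## 1. The angle frame

Capnogram corner angles are not well defined until the plot's aspect
ratio is fixed. The package adopts one frame everywhere: per breath,
time is affinely mapped to [0, 1] and pCO₂ divided by P_ref = 5 kPa
(configurable). In this frame an ideal square wave has vertical
transitions, so its alpha and beta corners are exactly 90°, and typical
healthy tidal breaths land near 100–105°. Tangents are least-squares
lines fitted over the central 60% of each phase's samples; angles follow
from θᵢ = atan(mᵢ):

* alpha = 180 − (θ₂ − θ₃), beta = 180 − (θ₃ − θ₄),
  delta = 180 − (θ₂ − θ₁), gamma = 180 − (θ₁′ − θ₄),
  where θ₁′ is the next breath's baseline tangent (falling back to the
  current one for the last breath of a recording).

Degenerate (near-vertical) tangents are handled in the limit
(θ → ±90°). One convention edge case: for a perfect step the phase-IV
tangent window of a standalone breath contains only the flat tail, so
the *fitted* θ₄ of an exact square wave is 0 rather than −90; the 90°
beta limit is a property of the angle formulas and is tested there.

## 2. Preprocessing

* **Denoise** — Hampel despike (window 5, 3×1.4826×MAD with a 0.3 kPa
  absolute floor, edges untouched) followed by a zero-phase spectral
  low-pass at 0.3×fs (3 Hz at 10 Hz), implemented as reflect-extended
  FFT truncation. Both stages are identity on already-clean signals, so
  the composed denoiser is an exact projection: applying it twice equals
  applying it once (to machine precision as long as the non-negativity
  clip does not engage). This idempotency is the reason a spectral
  projection was chosen over an IIR filter, which attenuates the
  passband a little more on every pass; the Hampel stage likewise leaves
  smooth extrema alone where a plain median filter would clip them.
* **Breath separation** — downward crossings of the mid-line of a
  rolling 10th/90th-percentile envelope (15 s window), with a hysteresis
  band of 10% of the local amplitude and a debounce: a candidate
  boundary counts only if the signal stays low ≥ 1.2 s (high ≥ 0.3 s).
  The debounce is what keeps swallow-type plateau interruptions from
  splitting a breath in two; its cost is that breathing faster than
  ~22 breaths/min would be under-segmented, acceptable for adult tidal
  breathing. First/last partial breaths are flagged incomplete and
  excluded (geometric features need both boundaries).
* **Phase segmentation** — on the derivative of a monotone-cubic
  (PCHIP) reconstruction evaluated on a fine grid: phase II starts where
  the derivative first exceeds 20% of the span's maximum positive
  derivative, phase III where it falls below 10% of that maximum, phase
  IV at the first later crossing of −20% of the maximum-magnitude
  negative derivative. Boundaries are clamped so each phase keeps at
  least two samples (a step transition collapses to the minimal
  2-sample phase); anything narrower raises a segmentation failure,
  never silent values. The continuous reconstruction matters: applying
  the same rules to raw sample differences at 10 Hz quantizes the
  tangent windows and biases angles by several degrees.
* **Quality control** (all thresholds are config fields; the rule
  *classes* are standard, the numbers are this package's operating
  point): amplitude < 1 kPa; duration outside [1, 15] s; cough = a
  negative plateau transient > 0.5 kPa recovering within 1 s; swallow =
  a plateau excursion to within 20% of baseline lasting ≥ 0.5 s;
  cardiogenic = 0.5–3 Hz band power exceeding 25% of the detrended
  central-plateau variance *and* a band RMS above 0.07 kPa (the floor
  separates genuine cardiogenic ripple, ~0.1 kPa RMS, from normal
  plateau texture, ~0.03 kPa). Recording-level: per-breath baseline
  trend > 0.1 kPa/min → condensation; fewer than 8 valid breaths →
  reject. Rules are evaluated independently and all violations reported.

## 3. Feature registry

87 per-breath features (44 raw-time + 43 time-normalized; breath
duration is identically one after normalization and is dropped), each
carrying one waveform-region tag. Median aggregation covers all 87;
sample SD (n−1) covers a designated 67-feature subset: all 44 raw
features plus the normalized shape families (angles, gradients, areas,
shape indices, texture) and the three normalized amplitude summaries —
the excluded normalized timing/position/ratio features duplicate the
dispersion information of their raw counterparts. With the 5
whole-recording metrics the vector length is 87 + 67 + 5 = 159. The
registry ships as versioned JSON (`data/registry_default_v1.json`) so
alternative compositions are testable without code changes.

Region tags follow the corner a feature measures: phase II gradients,
slope shape indices and the plateau's corner-curvature measures (chord
area, mean second derivative) are alpha-region; phase III/IV tangent
features beta; downstroke timing and landmarks gamma; baseline tangent
delta; the rest tag plateau/upstroke/timing/amplitude/area.

Time normalization interpolates each breath linearly onto a 100-point
unit-time grid and re-runs segmentation there; normalized band-power
uses a 2–12 cycles-per-breath band so the feature is invariant under
uniform time dilation. Plateau sample entropy uses m = 2,
r = 0.2×SD, capped at 5 where undefined.

## 4. The synthetic generator

The generator is phenomenological — no gas-exchange modelling — built so
every downstream geometric feature has an independent knob: constant
baseline (with an optional subject-varying linear tilt), normalized
logistic upstroke, a plateau line of slope `plateau_slope` (kPa per unit
normalized breath time) approached through an exponential rounding term
(`plateau_curvature`; depth fixed at half the line's total rise, so a
zero-slope plateau is exactly flat), logistic downstroke, ending exactly
at the set ETCO₂. Continuous recordings concatenate cycles
expiration-first with multiplicative lognormal per-breath jitter, then
inject artefacts (cough, swallow, condensation drift, cardiogenic
sinusoid) with every interval logged, then additive Gaussian noise. A
low-amplitude stochastic two-tone plateau ripple (default 0.035 kPa)
emulates the irregular fine texture of real plateaus; without it,
texture features are unrealistically deterministic. Ground truth —
detector-convention span boundaries, rule-based phase boundaries,
angle-frame tangents and angles, ETCO₂ — is computed on a dense
noise-free grid by an independent implementation of the same rule
definitions and stored in annotations. A single integer seed drives
split child streams (breaths, artefacts, ripple, noise), so recordings
are bitwise reproducible.

Cohort presets (healthy, asthma, CHF, acute and recovered pneumonia)
are tuned numerically so each preset's analytic alpha sits on its
target: 102.9° / 112.8° / 116.5° / 109.4° / 109.4°, in the ordering the
method is meant to resolve. Acute pneumonia carries a low ETCO₂
(3.5 kPa, consistent with type I respiratory failure); the recovered
preset raises it by 12.6%. The obstructive (asthma) preset differs from
healthy mainly in plateau slope, alpha-corner rounding and a prolonged,
slightly shallower phase II; between-subject spreads (slope CV 0.25,
fraction CV 0.18, upstroke/downstroke steepness CV 0.15/0.45, ETCO₂ CV
0.05, baseline-tilt SD 0.1 kPa per unit time) were calibrated at truth
level so the simulated effect-size structure is obstruction-like: the
strongest healthy-vs-obstructive effects concentrate in alpha-region
features (subject-level alpha d ≈ 2.4), beta and plateau effects follow,
delta effects stay modest. The downstroke CV is deliberately large
(inspiration is effort-dependent) and the baseline tilt is what keeps
delta/gamma angles realistically variable.

Study-level simulation adds clinical covariates with explicit
couplings: spirometry (FEV₁/FVC, % predicted FEV₁) noisily *decreasing*
in each asthma subject's true alpha; LVEF noisily *increasing* in alpha
for CHF; NT-proBNP independent of alpha; coupling strengths are
parameters, zero meaning independence. Pneumonia subjects record in two
windows (days 0–7 and 168–175) with the recovered ETCO₂ shift applied.
A lighter measurement-level generator (`simulate_etco2_recovery`)
produces per-recording ETCO₂ values directly for power studies of the
paired analysis.

**What the generator does not emulate** — real sensor transfer
functions, breath-to-breath autocorrelation, dysfunctional breathing
patterns, device condensation dynamics beyond a linear ramp, or true
physiological covariate scatter. Passing tests therefore demonstrate
that the pipeline recovers what this model encodes, not that it is
clinically validated.

## 5. Statistics

Two-sided throughout. Mann-Whitney U uses midranks; exact p by full
enumeration of group labelings when n ≤ 12 (the two-sided p is the
probability of a |U − μ| at least as extreme), otherwise a normal
approximation with tie and continuity corrections. Bonferroni
multiplicity defaults to the number of features screened. Cohen's d uses
the pooled (n−2) SD, sign preserved, |d| binned small/medium/large at
0.5 and 0.8. Pearson r carries a t-based two-sided p and the fitted line
for regression plots. The paired recovery analysis takes per-subject
window medians, relative change 100×(end−start)/start, cohort median of
per-subject changes, and an exact Wilcoxon signed-rank for n ≤ 25
(all-zero differences give p = 1 by convention; a sign test is available
as a config switch).

## 6. Problem sizes and verification

The shipped checks use desk-scale sizes chosen to exercise each claim:
angle-oracle equivalence on noise-free breaths at 25 Hz (≤ 1° across all
presets; at 10 Hz the PCHIP reconstruction of steep downstrokes biases
beta/gamma by up to ~2°, a documented resolution limit); parameter
recovery on 200 noisy breaths at 10 Hz (median alpha error ~1.3°, ETCO₂
~0.02 kPa); QC benchmarks on ~500 labelled breaths per artefact class
(cough/swallow rejection ≥ 90%, condensation ≥ 90% of recordings, clean
false rejection ≤ 5%); the healthy-vs-obstructive screen on 50
replicates of 20 + 20 subjects; recovery tracking on 100 replicates of
8 paired subjects. Randomness is always seeded; hypothesis-style
property checks are derandomised through fixed seeds.

## 7. Known limitations

* Angle accuracy at 10 Hz is reconstruction-limited for very steep
  downstrokes (beta/gamma up to ~2° bias); raw-time alpha is robust.
* The breath detector targets adult tidal rates (~8–22 breaths/min); the
  1.2 s debounce under-segments faster breathing.
* Swallows are occasionally rejected under a different label (cough or
  segmentation failure) when smoothing shortens the sub-threshold
  excursion; class-level rejection stays above the operating point.
* Registry composition (which features are SD-aggregated, region-tag
  assignments) is a design choice made once and versioned; other
  compositions are legitimate and supported as data.
* The generator's effect-size calibration is truth-level and
  obstruction-like, but no claim is made that simulated cohorts match
  any real population beyond the targeted medians and orderings.
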