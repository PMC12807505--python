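# Methods

This note records the models, conventions and numerical choices behind
partolab, what the synthetic-data generator does and does not emulate, and
the known limitations of the statistical procedures at the cohort sizes
this package targets.

## Telemetry representation and resampling

All internal times are seconds since the recording's lights-on reference
(ZT0); wall-clock times are converted once at the boundary
(`to_zt`, periodic with a 24 h period). Delivery annotations are whole
ZT minutes, reflecting the 1-minute accuracy of video-based pup scoring;
labor onset is the first delivery.

Pressure traces are resampled to exactly 1 Hz by averaging samples in
half-open bins `[t, t+1)`. Averaging (rather than decimation) is
anti-aliasing and preserves the mean of a constant signal exactly; the
half-open convention counts every sample once. Bins containing no samples
(telemetry dropouts) are filled by linear interpolation so the grid stays
uniform for windowing, but they are flagged, and any detected peak whose
apex falls in a flagged span is discarded — linear fill can fabricate a
plateau apex between equal flanking samples but never new extrema beyond
them.

## Contraction peaks

A contraction peak is a strict local maximum of the 1 Hz trace with

* height ≥ 40 mmHg — height is the absolute sample value, not
  baseline-subtracted; resting intrauterine pressure sits near zero
  relative to this threshold, so the distinction is immaterial in
  practice and the absolute reading keeps the criterion self-contained;
* topographic prominence ≥ 20 mmHg — the height of the peak above the
  higher of its two base minima, each base being the minimum between the
  peak and the nearest strictly higher sample on that side (or the trace
  edge).

Plateaus collapse to one peak at the plateau midpoint (floor division);
edge samples cannot be peaks (a local maximum needs two neighbors).
Detection is delegated to `scipy.signal.find_peaks`, whose height,
prominence and plateau conventions coincide with the definitions above;
the test suite verifies exact agreement (locations, heights and
prominences) against an independent O(n²) implementation written directly
from the definition, on a thousand random traces including ties and
plateaus.

Windows are half-open and partition the recording: pre-labor
`[start, onset)`, post-onset `[onset, onset + 2 h)`, and beyond
`[onset + 2 h, end)`. The per-animal outcome `P_i` is the arithmetic mean
of peak heights in the 2-hour post-onset window; animals with no peaks
there carry an explicit missing value rather than a zero — an animal with
no detectable contractions has no defined mean peak pressure, and the GLS
stage requires such animals to be excluded explicitly.

## Group tests

Cohorts of 6–9 animals per group put these tests squarely in the exact
regime, so the implementations are exact by construction rather than
asymptotic:

* **Fisher 2×2** — two-sided by the probability-mass rule: the sum of
  hypergeometric probabilities of all tables (margins fixed) no more
  probable than the observed one, with relative slack 1e−12 so floating
  point cannot flip a tie. Degenerate margins give p = 1 (the margins
  admit a single table). The onset dichotomy is strict: delivery *after*
  ZT3 means onset_zt > 3, boundary onsets count as before (the boundary
  is configurable).
* **Mann-Whitney U** — exact when the combined sample is ≤ 20 without
  ties, using the full null distribution of U from the standard counting
  recurrence (conditioning on whether the largest pooled value belongs to
  the first sample); two-sided p sums both tails by distance from
  n₁n₂/2. Otherwise a normal approximation with tie correction and **no
  continuity correction**: omitting it makes the two-group test
  algebraically identical to the tie-corrected Kruskal-Wallis chi-square
  test (H = z²), so the two procedures always reach the same decision on
  the same data — a property the tests assert. At 9 vs 9 the attainable
  exact level of the nominal 5% test is 0.0400.
* **Kruskal-Wallis** — tie-corrected H against chi-square with k − 1 df.
  All-identical data give H = 0 (the 0/0 limit), p = 1.

## The heteroscedastic GLS contrast model

Per-animal mean peak pressure is modeled with an intercept and two
knockout dummies (DRG, uterus); errors are independent normals with one
variance per treatment group. Estimation is iterative feasible GLS:

1. ordinary least squares for the initial coefficients;
2. group variances σ̂²_g = RSS_g / (n_g − 1) from within-group residuals;
3. weighted solve β̂ = (XᵀΩ⁻¹X)⁻¹XᵀΩ⁻¹P with Ω = diag(σ̂²_g(i));
4. repeat 2–3 until the maximum relative change in β̂ is below `tol`
   (default 1e−8, `max_iter` 100). A `one_step` option stops after the
   first reweighting; `omega=` fits with a known, fixed covariance.

Numerics: the weighted solve runs as QR least squares on the
√weight-scaled design rather than the normal equations, which stays
accurate when a nearly saturated group drives its variance estimate to
the floor (variances are floored at 1e−12 × the outcome's mean square to
keep Ω invertible). Standard errors come from diag((XᵀΩ⁻¹X)⁻¹) at the
final Ω; non-convergence is reported via `converged_ = False`, never
raised. Every group needs ≥ 2 animals with a defined outcome, else the
variance is inestimable and the design is rejected.

The Bessel-corrected denominator n_g − 1 (not n_g) is used for the group
variances: with 6–8 animals per group the uncorrected maximum-likelihood
denominator deflates the standard errors enough to push the one-sided
test's type-I error to ≈ 0.08–0.09 at nominal 0.05; with the correction
the test calibrates to ≈ 0.06 under an exchangeable null at the study's
group sizes (verified by simulation in the acceptance tests).
`variance_ddof=0` restores the plain mean of squared residuals.

One-sided tests address decreasing effects: H0: β ≥ 0 vs H1: β < 0, with
t = β̂/SE and p = P(T_{n−p} ≤ t). The lower-tail probability is reported
for every coefficient, including positive estimates (where it exceeds
0.5); a two-sided alternative is available. Degrees of freedom are
n − p with p = 3, the mean-model coefficients only — variance parameters
are not counted, and no Satterthwaite-type adjustment is applied.

**Known limitation.** Plug-in FGLS ignores the uncertainty of the
estimated group variances. Under strong heteroscedasticity (group SDs
10/25/30/35 at group sizes 8/7/6/8) the one-sided test for the contrast
weighted toward the smallest group remains mildly anticonservative
(empirical type-I ≈ 0.075 at nominal 0.05, measured over 40,000
replicates) with either variance denominator. This is inherent to the
t_{n−p} reference at these sample sizes; p-values near the threshold
should be read accordingly.

## Mechanoresponse classification

Sweeps are filtered with an 8-pole low-pass Bessel filter whose −3 dB
point is placed exactly at the 500 Hz cutoff (analog prototype,
bilinear transform with pre-warping; scipy's `norm="mag"`). Filtering is
single-pass with initial conditions matched to the first sample, so a
constant trace passes through unchanged and the measured gain at the
cutoff is 1/√2 within 1%. The baseline is the mean and sample SD
(n − 1 denominator) of the filtered current in `[onset − 35 ms,
onset − 5 ms)`; the peak amplitude is the largest |current − baseline
mean| over `[onset, onset + ramp + hold]`, where the ramp lasts
depth / (1 μm/ms) and the hold 125 ms. A sweep is a mechanoresponse only
if that amplitude **strictly** exceeds 5× the baseline SD ("exceeds"
read literally; a deflection of exactly 5 SD is not a response). Both
the mean and the SD come from the same filtered pre-stimulus window;
`filter_first=False` applies the rule to the raw trace instead.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

* multi-hour traces at ≥ 1 Hz: a low baseline (default 5 mmHg, Gaussian
  noise SD 1.5 mmHg) plus Gaussian contraction bumps of width 15 s;
* event times from a two-rate Poisson process — sparse before labor
  onset (2/h) and group-dependent after (30/25/15/8 per hour for
  control / uterus / DRG / combined knockouts) — thinned so centers stay
  ≥ 3 widths apart, keeping ground-truth peak counts well defined at
  1 Hz;
* hierarchical amplitudes: each animal draws a mean level from
  Normal(group mean, group `peak_amp_sd`) and individual transients
  scatter around it (SD 5 mmHg); both truncated at 0 (pressures are not
  negative). The between-animal spread is the generative counterpart of
  the group-dependent variance σ²_g the GLS model estimates;
* delivery records: onset ~ Normal per group (controls early,
  knockouts later and more variable: means ZT 1.5/1.8/2.8/3.0 h),
  6–9 pups, inter-pup gaps Normal per group (6/8/7/15 min) truncated at
  1 min, all rounded to whole minutes;
* patch-clamp sweeps at 20 kHz: Gaussian baseline noise, and for
  responsive sweeps an inward deflection rising linearly over the probe
  ramp and sustained through the 125 ms hold.

Default group amplitude means place the control at 100 mmHg with the
additive effects −16.01 (uterus) and −47.11 mmHg (DRG); absolute levels
are configurable, not canonical — the study conditions fix the detection
thresholds and effect sizes, not the absolute peak pressures. Note a
deliberate consequence: the combined knockout's default mean (36.88 mmHg)
sits *below* the 40 mmHg detection threshold, reproducing the "minimal
contractions" phenotype; cohorts generated at the defaults therefore
yield animals with undefined P_i. Validation experiments that need all
groups identifiable (parameter recovery) shift the control level to
140 mmHg so every group clears the threshold by > 6 SD.

Determinism: every animal consumes its own `SeedSequence(seed,
spawn_key=(animal_index,))` streams (onset, deliveries, trace), so output
files are byte-identical for identical seed + config and independent of
generation order. Fixed-precision CSV formatting makes whole-run outputs
byte-reproducible.

What the generator does **not** emulate: circadian or pharmacological
modulation of contractions, baseline drift and movement artifacts,
catheter failures other than uniform-random dropouts, biomechanics of the
uterine wall (transients are phenomenological Gaussians), or gestational
transcriptomics. Passing tests therefore demonstrate correctness of the
analysis pipeline under the assumed statistical structure, not robustness
to every artifact of real telemetry.

## Validation experiment sizes

The test suite runs desk-scale versions of every validation: exact
peak/oracle agreement on 1000 random traces (≤ 500 samples), GLS
closed-form equivalence on 100 random designs (1e−10), direct parameter
recovery over 500 simulated cohorts and end-to-end pipeline recovery over
200 generated cohorts (2 Monte-Carlo SE bands), type-I calibration over
2000 replicates per test, and 1000 noise-only sweeps for the classifier's
false-positive rate. Monte-Carlo checks use a single shared seed
constant; `scripts/acceptance.py` re-derives all of its substreams from
the `--seed` argument.
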