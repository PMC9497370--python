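# Methods

## Single cosinor

All rhythm fits use the fixed-period single-component cosinor: ordinary
least squares of `Y = M + β cos(ωt) + γ sin(ωt)` with ω = 2π/24 h⁻¹. The
period is never estimated — one day of 4-hourly samples cannot support a
free period, and the multi-day actigraphy records are analyzed at the same
fixed 24 h for comparability. Derived quantities: amplitude A = √(β²+γ²),
acrophase φ = atan2(−γ, β) wrapped to (−2π, 0] (midnight reference, so the
peak clock time is −φ·24/2π; reports additionally print degrees on
(−360°, 0] for actigraphy, following that literature's convention), percent
rhythm PR = 1 − RSS/TSS (identically the squared observed-vs-fitted
correlation), and the zero-amplitude F test
F = ((TSS − RSS)/2)/(RSS/(n−3)) on (2, n−3) df, requiring n ≥ 5.

Degenerate inputs are explicit errors rather than NaNs: fewer than four
distinct clock times (model under-determined), a constant response
(amplitude identically zero), or a rank-deficient sampling design. An exact
fit (RSS = 0 to machine precision) sets `exact_fit`; its p is reported as 0
and the Fisher z comparison refuses such fits (atanh(1) diverges).

Fits of hourly-binned activity use **bin-center times** (h + 0.5). Binning
a cosine over an hour shifts nothing at the bin center but would bias the
acrophase by half an hour (7.5°) if bin-start times were used.

## Population-mean cosinor and Bingham parameter tests

Per-subject fits are aggregated by averaging (M, β, γ) across the k
subjects of a group; the population amplitude/acrophase derive from
(β̄, γ̄). Between-subject phase scatter therefore shrinks the population
amplitude below the mean individual amplitude — intended behavior of the
estimator, not a bug (see "Known biases").

Group comparisons are t tests with df = k₁+k₂−2 on:

* mesor: difference of means over √(s²_M,1/k₁ + s²_M,2/k₂);
* amplitude: delta-method variance
  Var(Â) = (β̄²s_ββ + 2β̄γ̄s_βγ + γ̄²s_γγ)/(kÂ²);
* acrophase: Var(φ̂) = (γ̄²s_ββ − 2β̄γ̄s_βγ + β̄²s_γγ)/(kÂ⁴), with the
  difference wrapped to (−π, π].

When the acrophase test is significant at 0.05 the amplitude test compares
waves peaking at different times; the result carries
`amplitude_reliable = False` and report tables print that flag. A population
with zero amplitude has no acrophase; its amplitude/acrophase tests are
returned flagged undefined instead of raising, so a degenerate group does
not abort a report.

Measured operating characteristics under the study design (12 vs 11
subjects, 7-point schedule, null of identical parameters, 2,000 replicates):
rejection rates 0.04–0.05 for all three tests; the zero-amplitude F test
rejects at 0.046 over 10,000 flat-series replicates
(`analysis/04_operating_characteristics.py` recomputes these).

## Percent-rhythm comparison

Fisher z on the observed-vs-fitted correlations of two groupwise fits:
Z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), two-sided normal p.
Groupwise fits are computed on the **group-mean time profile** (per-bin mean
across subjects) with n = number of time bins; population tests always use
per-subject fits. With so few bins the z test is coarse — it is reported
because the study design calls for it, not because it is powerful.

## Nonparametric actigraphy metrics

Epochs are summed into hourly values per calendar day. Partial days at the
record edges are trimmed (they bias hour-of-day means); interior gaps
instead flag any hour missing more than 20% of its epochs, and flagged
hours are never silently zero. With x_i the N hourly values, x̄_h the 24
hour-of-day means and x̄ the grand mean:

    IS = (N Σ_h (x̄_h − x̄)²) / (24 Σ_i (x_i − x̄)²)
    IV = (N Σ_{i≥2} (x_i − x_{i−1})²) / ((N−1) Σ_i (x_i − x̄)²)

IS is 1 for a perfectly repeated daily pattern and ≈ 1/(number of days) for
white noise; IV → 2 for white noise and 2(1 − cos(π/12)) ≈ 0.068 for a pure
hourly-sampled 24-h cosine. Both are undefined (explicit error) for a
constant record, and both are invariant under affine count rescaling.

M10 and L5 are window **totals** over the hour-of-day mean profile (10-h and
5-h windows, 1-h steps, wrapping across midnight) — the scale on which such
tables are printed. The relative amplitude uses the per-hour window means,
RA = (M10/10 − L5/5)/(M10/10 + L5/5): on totals a constant profile would
score (10c−5c)/(10c+5c) = 1/3 rather than 0, so means are the only choice
that makes RA a pure rhythm contrast on [0, 1].

## Mann–Whitney U

U from midrank sums; Z from the tie-corrected normal approximation with a
0.5 continuity correction (the convention at these sample sizes); and, for
pooled samples of at most 12, an exact two-sided p by full enumeration of
label assignments (conditional on midranks, U is symmetric around n₁n₂/2,
so the two-sided p counts assignments at least as far from the center).
Both p values are reported; the exact one is the reference at pilot-study
sizes.

## ΔΔCt reduction

Duplicate wells collapse to their mean Ct, flagged discordant above a
1-cycle spread (a QC convention of this package) and flagged singleton when
a replicate is missing. ΔCt = Ct_target − Ct_B2M per sample;
ΔΔCt subtracts the subject's reference ΔCt; expression = 2^−ΔΔCt assumes
the amplification efficiency of 2/cycle that the assay design establishes.
The reference condition is the subject's **earliest clock hour** of the
sampling day (configurable to the subject's mean ΔCt). Per-subject
referencing preserves exactly what the cosinor stage consumes — the
within-subject 24-h shape — and makes expression at the reference time
exactly 1, at the cost of putting all profiles on subject-relative scales;
group-mean expression profiles are therefore shape comparisons, not
absolute-level comparisons. Batch shifts that move target and housekeeping
Ct alike cancel identically.

## Synthetic cohort generator

The generator emulates the study design end to end: 12 ADHD / 11 control
subjects; 5 days of 1-min actigraphy; cortisol and melatonin sampled at
08, 12, 16, 20, 22, 00, 04 h (4-hourly plus the 22:00 sample covering the
dim-light-melatonin-onset window); qPCR at the 6 four-hourly times. The
22:00 sample is modeled but no DLMO statistic is computed.

Group-level rhythm parameters default to the published chronometric values
(cortisol in µg/dL: ADHD M = 0.1217, A = 0.1232, φ = −2.1367 rad; control
M = 0.1699, A = 0.1347, φ = −1.7763; melatonin in pg/mL: ADHD M = 17.757,
A = 12.831, φ = −0.4904; control M = 12.670, A = 6.280, φ = −0.3088).
Between-subject SDs default to 20% of each parameter — a typical
coefficient of variation for salivary endocrine parameters — except the
actigraphy acrophase SDs, where the published per-group SDs (10.18° and
13.81°) are used directly. Residual noise: 0.05 µg/dL (cortisol), 2 pg/mL
(melatonin), 0.1 cycles of technical Ct noise per well (qPCR). Hormone
concentrations are truncated at 0 by default (assays cannot go negative);
`truncate=False` gives the purely additive-Gaussian variant used in the
cortisol recovery protocols. An `arrhythmic` flag forces zero amplitude
with noise retained; the default ADHD clock-gene specs are arrhythmic while
the control specs oscillate with mesor 1.0 and relative amplitude 0.5
(peak/trough ≈ 3; BMAL1 peaking 08:00, PER2 16:00).

Activity counts (per 1-min epoch) follow a rectified-cosine mean
max(0, M + A cos(ωt+φ)) with negative-binomial noise (dispersion 8) — real
accelerometry counts are nonnegative and overdispersed — multiplied by a
mean-one lognormal AR(1) modulation per clock hour (log-SD 0.48, lag-1
correlation 0.4) representing activity bouts and day-to-day irregularity.
The modulation is mean-preserving, so fitted acrophases stay unbiased,
while IS and IV land near the ~0.6 magnitudes real wrist records show
instead of their noiseless limits (1 and 0.07). Count parameters (ADHD
M = 33, A = 30; control M = 35.4, A = 32 counts/epoch) put hourly M10/L5
totals on the published scale. Illuminance is lognormal around 250 lux
(07:00–21:00) and 0.5 lux at night.

qPCR wells encode expression as Ct_target = Ct_B2M + 5 − log2(expression),
with B2M constant at Ct 20 up to technical noise, so the ΔΔCt reduction
recovers the generating cosine up to the reference normalization.
Demographics and questionnaire scores are Gaussians at the published group
means/SDs, clipped to each scale's range, and treated as opaque numbers.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: sleep/wake bout structure and non-wear
missingness, weekday/weekend differences, assay detection limits and
plate effects beyond a global shift, pulsatile cortisol secretion
(the cortisol awakening response in particular), RNA-quality variation,
and any correlation between levels (activity, hormones, expression are
generated independently given the group).

## Known biases and numerical choices

* Population amplitude is shrunk by between-subject phase scatter
  (vector averaging) and slightly inflated by finite-k noise; at the
  melatonin defaults the net effect is ≈ −1.4% (recovered 12.66–12.78
  against 12.83 across seeds), and truncation at 0 adds ≈ +0.5% to the
  melatonin mesor. Both are documented by `analysis/03_parameter_recovery.py`,
  which prints each estimate with its Monte-Carlo SE.
* Acrophases are averaged circularly (unit-vector mean) everywhere;
  acrophase differences are wrapped to (−π, π] before testing.
* The pipeline skips the chronometric (Bingham) comparison of gene rhythms
  whenever either group lacks a significant groupwise rhythm, and reports
  the skip in-table; hormone comparisons always run.
* Significance is α = 0.05 throughout with no multiplicity correction —
  a deliberate mirror of the exploratory pilot design, not a recommendation.
* Verification problem sizes: 100 simulated cohorts per recovery target,
  10,000 replicates for the F-test level, 2,000 for the Bingham levels,
  100 studies for the clock-gene scenario — sizes at which Monte-Carlo SEs
  are a few percent of each target while the whole battery runs in minutes.

## Limitations

Fixed 24-h period only (no periodogram, no multi-component cosinor, no
confidence ellipses); no sleep scoring or DLMO estimation; groupwise
percent-rhythm values at 6–24 bins are coarse and their F tests have few
denominator df; the Mann–Whitney exact enumeration is limited to pooled
n ≤ 12 (beyond that the tie-corrected normal approximation stands alone).
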