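# Methods

`circarun` analyses minute-binned wheel-revolution recordings of mice kept
either on a 12:12 light:dark schedule (LD, lights-on defining Zeitgeber time
ZT0) or in constant darkness (DD, free-running). This note describes the
models, the estimators, the synthetic data the tests run on, and the design
choices made where the procedures admitted more than one reasonable reading.

## Preprocessing

Raw recordings are nonnegative integer counts per minute. The first *n*
complete days are discarded as habituation (3 days for between-subjects
panels, 7 for the within-subjects trisomy panel), and trailing partial days
are truncated so that every per-day statistic is computed on whole days.
Fractional counts are rejected rather than rounded — wheel revolutions are
counts. The CSV reader fills documented gaps with an explicit missing
marker; all analysis operations refuse recordings containing it, because the
regressions below assume a complete, equispaced design grid. ZT phases are
half-open — light is ZT [0, 12), dark ZT [12, 24) — so the two phases
partition each day with no bin counted twice.

## Periodometry

For a candidate period τ the series Y(t) is regressed by ordinary least
squares on {1, cos(2πt/τ), sin(2πt/τ)}; the quadrature pair gives the
amplitude A(τ) = √(β² + γ²). A single sine with no intercept cannot
represent an arbitrary phase or a nonzero mean, so the intercept +
quadrature form is used throughout (this is standard harmonic regression;
the sine-only notation is a simplification of the same model).

The zero-amplitude test compares the full fit against the intercept-only
model:

    F = ((SSE₀ − SSE₁)/2) / (SSE₁/(n − 3)) ~ F(2, n − 3)

under the null of no oscillation at τ. Numerically exact fits (SSE₁ ≈ 0)
are reported as F = ∞, p = 0 when the oscillation explains real variance
and as F = 0, p = 1 for constant input.

`frequency_decomposition` runs a two-stage search over a 20–28 h window
(the plausible range for mouse circadian rhythms): first the Fourier
periods T/k of the record length, then a refined grid (default 0.01 h)
spanning the interval between the coarse maximum's neighbouring Fourier
periods. Fourier spacing alone near 24 h is 0.2–0.4 h for 7–14-day records
— too coarse to support period comparisons between groups — hence the
refinement stage. Ties on amplitude resolve to the smallest τ for
determinism. The harmonics τ/2, τ/3, τ/4 of the selected fundamental are
then each given the zero-amplitude test at α = 0.05, uncorrected for
multiplicity across harmonics. On finite records the amplitude spectrum of
a multi-component signal shows leakage between non-orthogonal components,
so the peak of a composite signal sits exactly at the generating period
only asymptotically; the tests account for this by using 10–12-day records
where sub-0.05 h accuracy is asserted.

## Cosinor rhythmometry

At the subject's fundamental period the single-component cosinor

    Y(t) = M + A·cos(2π(t − φ)/τ) + e(t)

is fitted on the linearisation M + β·cos(ωt) + γ·sin(ωt), with
A = √(β² + γ²) and the acrophase φ = atan2(γ, β)/ω mapped into [0, τ).
Time is measured from ZT0 (LD) or CT0 (aligned DD), so φ is directly the
latency from lights-on (or circadian midnight) to peak activity, in hours —
not the negative-radian convention some cosinor software reports. Standard
errors come from the OLS covariance by the delta method. The fit is applied
to the minute-binned counts pooled across all retained days.

Goodness of fit is checked with the Wald–Wolfowitz runs test on the
residual signs. Exact zeros are dropped first (ties are common with integer
counts). The two-sided p is 2·min(lower tail, upper tail) of the run count,
computed from the exact combinatorial run distribution when the signed
residual count is ≤ 20 and from the normal approximation with continuity
correction otherwise. When every residual shares one sign the conditional
run distribution is degenerate, so the unconditional sign-pattern
probability 2^(1−n) is reported for that branch. Subjects whose runs test
rejects are flagged `poor_fit` but retained — fit quality is reported, not
used as an exclusion criterion.

## Free-running analysis

Daily activity onsets are detected with a relative-threshold rule: the
series is smoothed with a 15-min centred moving average, and the onset is
the first bin at or above 25% of the search window's mean rate that stays
above threshold for ≥ 30 min after ≥ 60 min below it. The candidate from
the smoothed series is refined to the first raw bin above threshold, which
makes the detector exact on square-wave fixtures. Offsets are defined
symmetrically (end of the sustained bout); bouts censored by the record end
yield no offset. Detection runs twice: calendar-day windows give initial
candidates, a straight line through them predicts each day's onset, and the
search repeats in a one-day window centred on the prediction so that onsets
drifting across midnight (τ far from 24 h) stay correctly assigned. The
slope of the final regression of within-day onset time on day number is the
daily drift, (τ − 24)·60 min/day for a clean free-runner — an estimate of
the period independent of the periodogram, and the two are required to
agree on simulated cohorts. The threshold is relative, so detection is
invariant to uniform count scaling. Because only the use of a regression
line is documented for this step in the source protocols, the concrete
detector above is this package's own fully-specified reconstruction.

One circadian hour is τ/24 conventional hours. `align_to_ct12` divides the
time axis by that factor and shifts it so the circular mean of the onset
phases maps to CT12, the conventional phase of activity onset in nocturnal
rodents. Counts are redistributed into circadian-minute bins by
interpolating the cumulative count curve at the mapped bin edges — this
conserves the total count exactly (the last edge evaluates to the total),
at the cost of fractional counts in the CT frame. Truncation to whole
circadian days is a separate, optional step so the conservation contract
stays exact. The alpha (active) phase of each circadian day is the window
from CT12 to CT12 plus the mean onset-to-offset duration in circadian
hours; rho is the remainder, computed as day total minus alpha so that
alpha + rho equals the day total identically.

## Cohort statistics

Daily summaries are per-day light/dark (LD) or alpha/rho (DD) totals
averaged over retained days, with the percentage of daily activity in the
inactive phase; a zero-activity day yields 0% with a flag.

Outcome values are screened per group with the ROUT procedure specialised
to the constant model (the screened quantities are scalar per-subject
outcomes): robust centre = median, robust scale RSDR = 68.27th percentile
of absolute residuals × N/(N−K), candidates = the ≤ 30% most extreme
points, flagged by the FDR step-up rule at rate Q (default 5%). One
numerical choice departs from the textbook recipe: the t reference uses the
effective degrees of freedom of the percentile-based scale estimator
(≈ 0.54·N, from the asymptotic variance of the 68.27th percentile of a
half-normal) rather than N−K. A percentile estimate of scale is
substantially noisier than a standard deviation, and pretending otherwise
inflates the clean-data false-flag rate above the nominal Q; with the
effective df the screen flags something in ~2% of clean Gaussian samples
at n = 20, Q = 5%, while still flagging gross outliers at p ≪ Q/N.
Flagged values are excluded from downstream ANOVA by default with the flag
trail preserved in the output table; a per-group cap on exclusions is
available but off by default.

The mixed ANOVA is the classical univariate split-plot formulation — the
one whose denominator degrees of freedom match reports like F(6, 192) —
not a REML mixed model. It is computed in two error strata: between-subjects
effects are tested against subject-within-groups variation (a factorial
ANOVA of the per-subject means, sums of squares scaled by the number of
within cells), and within-subjects effects plus their interactions with
between factors are tested against the subject × within residual after
subject-centring. Type-II sums of squares with sum-to-zero contrasts are
used, so mildly unbalanced group sizes (after outlier exclusion) are
handled; the implementation is verified against an independent mixed-ANOVA
routine on one-between/one-within designs. No sphericity correction is
applied by default. A preliminary full-factorial ANOVA including sex is
provided so cohorts can be collapsed across sexes when no sex effect or
interaction appears. Post hocs are pairwise t tests with Bonferroni
adjustment over exactly the requested contrast family (the family is a
configuration choice, not inferred). Group-versus-control effect sizes are
summarised as 100·(group − control)/control per measure and condition,
with zero-control cells reported missing.

## Synthetic data

The generator draws counts per minute from a negative binomial with mean

    λ(t) = max(0, M + A·cos(2π(t − φ)/τ)) · mask(t)

and variance λ + λ²/dispersion, where mask(t) multiplies the rate by
`light_mask` during ZT [0, 12) of LD recordings. Negative-rate rectification
(rather than an exponential link) keeps M and A on the count scale the
cosinor estimates; the negative binomial (default dispersion 5, Poisson as
the dispersion → ∞ limit) reflects the burstiness of wheel running.

The genotype presets use a baseline of M = 7, A = 21 counts/min: with
rectification this gives a ~14.6-h active phase, a genuinely quiescent rest
phase and ~15,000 revolutions/day at a 28 revs/min peak — the shape and
scale of young C57BL/6J wheel output, and a waveform on which
threshold-based onset detection is meaningful. Group effects are
multiplicative activity scalings (scaling a rectified waveform scales the
fitted MESOR and amplitude by the same factor and leaves acrophase and
onset shape unchanged) plus period shifts in DD: controls free-run at
23.7 h; knockout and overexpressing groups at 23.9 h (period lengthening);
the overexpressor is scaled 0.6× its control (a 40% amplitude deficit in
both conditions); the knockout is 0.8× in LD but 1.3× in DD
(LD hypoactivity, DD hyperactivity); the trisomic panel scales 0.55× with
the gene-dose-corrected group intermediate at 0.8×. All magnitudes are
package defaults documented as synthetic — the source studies report no
per-animal variance components, so the between-animal jitter (lognormal
σ = 0.15 on MESOR and amplitude, 0.5 h wrapped-normal on acrophase) is
likewise a package choice. A deterministic square-wave profile (pure
alpha/rho structure) is provided for the onset-detection fixtures, where
every expected value is exact.

What the generator does **not** emulate: ultradian bouts and
wheel-mechanics autocorrelation, transients and aftereffects around
lighting transitions, age-dependent waveform change, masking dynamics
beyond a static light multiplier, and any mechanistic clock model. Passing
tests therefore demonstrate estimator correctness and calibration on data
satisfying the model assumptions, not robustness to every pathology of real
actigraphy.

## Problem sizes and determinism

The test and acceptance workloads use 100-subject recovery cohorts
(10 simulated days each), 2000-replicate calibration runs at 3 days ×
10-min bins, 200-replicate power studies at n = 15/group × 7 days, and
500-replicate outlier screens — sizes at which every Monte Carlo bound
asserted has comfortable binomial slack. All randomness flows through
explicit seeds (per-subject seeds spawned from a master seed), so every
pipeline output is bit-for-bit reproducible; tie-breaks (smallest τ,
first qualifying onset bin) are deterministic by construction.

## Known limitations

- The periodogram assumes a single dominant near-24-h component;
  multi-component or damped rhythms are out of scope.
- The cosinor is the population-standard single harmonic; waveforms far
  from sinusoidal (e.g. strongly masked LD profiles) yield amplitude
  estimates that are best understood as the first Fourier coefficient, and
  the runs test will (correctly) flag the lack of fit.
- Classical split-plot ANOVA requires complete within-subject designs;
  subjects missing a within cell are rejected rather than imputed.
- ROUT is implemented for the constant model only, matching its use on
  scalar per-group outcomes; the general nonlinear-regression form is not
  included.
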