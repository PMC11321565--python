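# Methods

This note records the statistical models, conventions and numerical choices
behind `hivetrax`, and what the synthetic data generator does and does not
emulate.

## Event processing

**Direction inference.** A dual-antenna tunnel reader produces a time-ordered
stream of raw reads per tag. Consecutive reads on opposite antennas within a
pairing window (default 2 s) form one crossing: outer-then-inner is an
arrival, inner-then-outer a departure, stamped at the later read. Any read
that cannot be paired becomes an `unknown` registration; every raw read
contributes to exactly one output record, so read counts are conserved.

**Timezone.** Registrations are logged in UTC and analysed in local civil
time. The default policy is a fixed +2 h offset (Swedish daylight-saving
time, which covers a May–August season); a +1 h winter-CET policy is
available. Fixed offsets keep the hour-of-day covariate free of
daylight-transition artefacts.

**Diurnal intervals.** Half-open, left-closed bins on the local clock:
MORNING [06,11), MIDDAY [11,16), EVENING [16,21), NIGHT [21,06). The bins
partition the 24-h clock; a flight is labelled by its departure time.

**Hourly count table.** All movement directions are counted (unknown
directions included — with imperfect readers they carry most of the signal),
summed per hive × date × hour, and zero-filled so every retained date
contributes exactly 24 rows per hive. Calendar dates within two days after a
cohort tagging event are excluded apiary-wide: entrance traffic there
reflects tag-related evictions rather than normal activity. Hourly
temperature, wind and humidity are means of the 5-minute records, rain is
the hourly sum; hours with fewer than 6 of 12 expected records get NA
covariates. The season of a row is spring before the summer tagging date and
summer after; age is whole days since that season's tagging event (the
response is per hive-hour, so age is cohort age, not an individual age).
Because no Mel drones can be tagged in spring (their drone production starts
later), spring counts for Mel hives are set NA in drone tables.

By default the grid covers the tagged (direction-reading) hives; these are
the levels of the colony random effect. Registrations at drift-target hives
are tallied in the run report.

## Flights

A departure and its next arrival (at any hive, drift flagged) form a flight;
a departure superseded by a later departure is reported unpaired, since a
new departure proves an unrecorded return. Unknown-direction records are
ignored for pairing but retained in the report. Pairs spanning more than 24
h (configurable) are treated as detection failure, not flights. Duration
categories are left-closed: [0,3), [3,10), [10,30), [30,60), [60,∞) minutes,
interpreted for drones as defecation/orientation exits, orientation flights,
and short/long/very long mating flights; worker flights use the same bins
for comparison only.

## Survival

Lifespan is operational: whole days from tagging to the last registration at
any hive. Monitoring in the motivating design continued 19 days past the
last registration, so by default every record is treated as an observed
endpoint; the API carries an event indicator for censored use. The
Kaplan–Meier estimator is the standard product-limit form with Greenwood
variance (ties as simultaneous events); with no censoring it equals the
empirical survival function exactly. The log-rank test uses the summed
observed-minus-expected counts with hypergeometric covariance over the first
k−1 groups; p-values come from the χ²(k−1) upper tail. Printed percentages
round half-up to one decimal.

## Classic tests

The Mann–Whitney statistic follows the rank-sum-minus-n₁(n₁+1)/2 convention
(identical to the U count), with midranks for ties. The exact two-sided p is
computed from the null distribution of U (counting recursion) when
n₁+n₂ ≤ 14 and the pooled sample is tie-free; otherwise the normal
approximation with continuity and tie correction is used — the two agree to
well under 0.01 by n₁,n₂ ≈ 20. Spearman's ρ is the Pearson correlation of
midranks and is NA (not 0) for a constant series. Per-day weather
correlations use all 24 hours of each day with at least 3 valid hours,
counts pooled within subspecies; medians and IQRs across days are the
summary. The factorial ANOVA uses Type-II sums of squares computed as
residual-sum-of-squares differences between nested least-squares fits (each
main effect adjusted for the other, the interaction for both), which
reduces to sequential SS in balanced designs; the count response is
log(y+1)-transformed by default so zero counts stay in the analysis
(configurable to log for strictly positive aggregates). Tukey HSD uses the
Studentized-range distribution with the Tukey–Kramer standard error for
unequal cells. The ANOVA observational unit is the hive × date × interval
aggregate count.

## The zero-inflated NB1 mixed model

Conditional on random intercepts u the hourly count is

* structural zero with probability p, logit p = γ·hour (numeric 0–23, no
  intercept). The science behind the term: the busier the entrance, the more
  likely the reader fails to register tags, so excess zeros track the
  diurnal traffic clock. A consequence of the no-intercept form is that p is
  pinned at 0.5 for hour 0; the term is a monotone traffic proxy, not a
  calibrated miss-rate model.
* otherwise NB1: size r = μ/(φ−1), success probability 1/φ, so E = μ and
  Var = φμ with φ ≥ 1 estimated on the unconstrained log(φ−1) scale. As
  φ→1 the pmf tends to Poisson; the implementation switches to the exact
  zero-inflated-Poisson limit when φ−1 < 1e−10.
* log μ = x'β + u_colony + u_season with independent normal crossed
  intercepts, variances optimised as log standard deviations with boundary
  detection at e⁻¹⁰.

Fixed effects: Timeinterval enters as four cell means (no global
intercept), Subspecies as a single Mel-vs-Buck contrast, the environmental
covariates (temperature, light, wind, rain) centred at their analysis-set
means, age and hour on their natural scales; interactions are elementwise
products of the (centred) parents.

**Estimation.** The marginal likelihood integrates the 6-dimensional
random-intercept vector out by a joint Laplace approximation at the mode of
the penalised log-likelihood; the mode is found by damped Newton steps
(the 6×6 curvature is assembled from per-row second derivatives in the
linear predictor). The outer optimisation is L-BFGS-B with the exact
analytic gradient of the Laplace objective — the envelope term plus
implicit differentiation of the log-determinant correction, which requires
third derivatives of the conditional log-likelihood (trigamma/tetragamma
evaluated by recurrence + asymptotic series). The fixed-effect block is
whitened by a QR factorisation of the design before optimisation; raw
covariate scales (days, W/m², km/h) otherwise stall the line search.
Restarts from perturbed starts are attempted on failure and non-convergence
is always reported. The parameter covariance is the inverse observed
information (central differences of the analytic gradient).

**Inference.** Wald intervals use Satterthwaite-type effective degrees of
freedom: df_j = 2V_jj²/Var(V_jj), with Var(V_jj) from the delta method over
the variance-component estimates. Coefficients estimated within colonies
get essentially normal intervals; cluster-confounded coefficients (the
interval cell means and the subspecies main contrast) get t intervals with
df ≈ 5–7. AIC is −2ℓ + 2k with k counting fixed effects, the zero-inflation
slope, the dispersion and both variance components. Backward selection
compares the maximal specification, the rain-family drop (rain main effect
and subspecies:rain), the temperature:light drop, and both drops, all on
the identical analysis set; ties go to the smaller model. The selected
drone specification drops the rain family and keeps temperature:light; the
worker variant keeps rain and its subspecies interaction.

**Known limitations.** With 4 colonies and 2 seasons the maximum-likelihood
variance components are biased low (no REML is offered), which has two
visible consequences at that design, confirmed by simulation at the study
scale: the interval cell means absorb a small shared upward bias
(≈ +0.05 on the log scale, the Jensen compensation exp(σ²/2) for the
underestimated variances), and intervals for the cluster-confounded terms
(interval cell means, subspecies main effect) cover a true value in roughly
78–80% of replicates rather than 95%, even with the Satterthwaite
correction. Within-colony effects — age, the weather covariates and all
interactions, which carry the scientific conclusions — are unbiased and
their intervals cover at 90–100%. Contrasts between subspecies should be
judged from the interaction terms, not the subspecies main effect.

## Synthetic data

The generator emulates the whole observation chain at the study's default
scale: two tagged hives per subspecies plus drift-target hives, 30 drones
and 20 workers tagged per hive per cohort (spring 18 May, summer 14 June;
no Mel drones in spring), gamma lifespans moment-matched to group means/SDs
of 31.5±21.6 d (spring drones), 15.8±15.4 d (summer drones) and
11.6±10.4 d (workers), first activity at a mean age of 5 days. While alive,
a bee emits exits from an inhomogeneous Poisson process whose hourly
log-rate is linear in temperature, light, wind and rain with diurnal
interval offsets peaking mid-afternoon — the same log-linear form as the
count model, so end-to-end recovery is internally consistent. Flight
durations come from a five-category mixture whose weights tilt longer with
age; drifting flights return to a uniformly chosen foreign hive. Weather is
a seasonal+diurnal temperature sinusoid with AR(1) noise, a solar-elevation
light proxy with daily cloud, gamma wind and Bernoulli-gamma rain on wet
days. Detection gives each crossing both-antenna reads, a lone read, or
nothing; the miss probability is logit-linear in the true traffic of that
hive-hour, so the three outcome probabilities sum to one at every traffic
level and zeros inflate exactly where traffic is high. Everything is
deterministic given a seed, and truth records (death days, passage lists,
per-crossing outcomes, generating parameters) are written alongside.

What the simulator does not emulate: tag loss and tag-induced mortality,
misread tag IDs, bees crawling under the reader, weather shared imperfectly
across hives, per-bee behavioural heterogeneity beyond age, and drone
congregation dynamics. Passing tests on synthetic data therefore
demonstrate the correctness and calibration of the algorithms under the
stated generative assumptions, not the field accuracy of the hardware.

## Problem sizes and determinism

The test suite exercises the count model at the study scale (4 colonies × 2
seasons × 60 days per season × 24 h ≈ 11,500 rows), with 50 replicates for
parameter recovery and 20 for model selection; the demo pipeline uses a
74-day window. Pipeline runs are deterministic given configuration and
seed, with every stage cached as plain CSV so any intermediate can be
inspected or re-derived.
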