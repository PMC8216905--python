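# Methods

## Temperature regimes

The *current* regime is a weekly climatology: daily mean temperatures are
averaged in two steps (per calendar day within each year, then across
years — so years with denser records do not dominate), held on a 366-day
calendar (Feb 29 averaged over leap years only), and binned into calendar
weeks anchored at January 1. Weeks 1–51 are 7-day blocks; week 52 is the
mean of the final nine days (366 − 51·7 = 9). The *future* regime adds a
constant +4 °C to every weekly mean, the RCP8.5-like end-of-century
offset.

Hourly setpoints put the daily minimum (w̄ − 3 °C) at 00:00 and the
maximum (w̄ + 3 °C) at 12:00, changing by exactly 0.5 °C per hour; the
24 hourly values of any day average exactly to the governing weekly mean
w̄, and the weekly mean switches only at a week's first day at 00:00.
Chamber physics (thermal inertia) is out of scope: setpoints are taken as
achieved.

Two week-numbering anchors are supported, because the mapping from the
experiment's own weeks (week 1 = the week the organisms entered the
chamber, 2017-11-14) onto the Jan-1-anchored climatology weeks is not
uniquely determined: the default (`week_anchor="start"`) holds each
7-day experiment block at the weekly mean of the calendar week containing
the block's first day; `"calendar"` switches values at calendar-week
boundaries instead.

A packaged sinusoidal climatology,
T(d) = 9.2 − 9.0·cos(2π(d − 15)/365.25) °C, serves as a central-European
stand-in (annual mean 9.2 °C, coldest mid-January); any daily CSV record
can replace it via `build_daily_climatology`.

## Photoperiod regimes

Sunrise and sunset follow the NOAA solar calculator: Julian-century
polynomial series for the sun's mean elements, equation of time from
obliquity and eccentricity, and the hour angle at zenith 90.833°
(refraction + solar semidiameter). Both sites use fixed CET (UTC+1) all
winter; daylight-saving time is deliberately ignored so the light program
stays continuous through late March. Schedule tables round times to the
nearest minute; internal computations are unrounded.

Lamp intensity is a dimensionless fraction in [0, 1] (LED spectra and lux
are out of scope). The text "gradually increasing … for 1 hr before the
lights were completely on" is ambiguous about the ramp anchor; the package
anchors the dawn ramp at [sunrise − 1 h, sunrise] (full intensity exactly
at sunrise) and the dusk ramp at [sunset − 1 h, sunset] (darkness exactly
at sunset). A consequence used as a test oracle: the integral of the light
fraction over a day equals sunset − sunrise exactly. Constant darkness is
identically zero.

The independent check for the solar geometry is a second implementation
from a different formula family (the Spencer Fourier-series fractional-year
expansion). The two agree within ~4–5 minutes of day length over the
experiment window; tests allow 6 minutes.

## Synthetic data

The generators realize the statistical structure the detector and models
assume; they are not mechanistic models of bee thermoregulation or crocus
physiology.

**Telemetry.** 12 sensors per colony, samples every 3 h, day boundary at
00:00. A per-colony permutation assigns sensors to ranks; rank 0 is the
designated core. On brood days the core holds 34.5 °C with a 1.0 °C daily
range (within the 1–2 °C biological band; ≥ 32 °C, so it passes the
detector); on broodless days the warmest sensor follows the winter cluster
at 24 °C with a 4 °C range (so it fails the 2 °C amplitude rule). Lower
ranks sit 1.5 °C per rank cooler, floored at the chamber setpoint — the
gradient guarantees a unique daily maximum sensor and exercises the
selection rule; the true spatial sensor arrangement in a hive is unknown,
so this is a stand-in. After a planned death day all sensors decay
exponentially (default 1.0/day) toward ambient and are capped at 17 °C, so
the censor rule fires deterministically on the death day itself. Gaussian
sensor noise (default sd 0.2 °C) is added *before* 0.5 °C quantization
(hardware order); quantization can be disabled for exact round-trip
property tests. Brood plans are **treatment-independent** by design: the
study found brood onset patternless across treatments, and keeping the
generator's truth null for the onset and brood-proportion models makes the
calibration checks meaningful. Power examples inject effects explicitly.

**Flowering.** Discrete weekly hazard
h(w) = 1 − exp(−h₀·exp(β_T·GDD(w) + β_P·L(w))), with GDD(w) the cumulative
weekly mean above a 0 °C base (no thermal-time model is published for this
system; the hazard's only job is to order regimes correctly) and L(w) the
day length at the week's first day. Defaults h₀ = 0.02/week,
β_T = 0.025 per °C-week, β_P = 0.08 per hour were chosen so that, under
the packaged climatology, the current-regime central-European cell flowers
around week 12 with ~85 % of bulbs flowering by week 22 and the warmed
regime flowers roughly four weeks earlier with ~100 % — the qualitative
pattern of the study. Under darkness an independent
Bernoulli(0.25) marks never-flowering bulbs (resource-starved, censored);
with β = 0 the law reduces to a geometric distribution, which is the
distributional test oracle. Every non-event is censored at the final week.

**Heights and weights.** Heights are Normal per cell with additive
defaults (base 9 cm, +2 cm warming, +4 cm etiolation under darkness,
+1.5 cm central photoperiod), a 0.6 cm between-arena random intercept and
1 cm residual sd. Daily weight change is −28.84 g on brood days and
−20.15 g otherwise (the study's reported means) plus Normal(0, 2 g) noise;
days from death on are omitted.

**Study bundle.** 2 × 3 cells × (4 colonies + 4 pots × 4 bulbs) = 24
colonies and 96 bulbs over 2017-11-14 … 2018-04-16 (154 days, 22 weeks).
One colony per cell descends from an artificial swarm, as in the study
design. Per-unit RNG streams derive from `SeedSequence(seed, spawn_key)`,
so adding units never perturbs existing ones, and a manifest records seed
and config hash.

## Brood detection

Per colony × sensor × day: max, min, mean of the available samples (8 when
complete; partial days are kept but flagged, and can be excluded by
config). The sensor with the highest daily maximum is selected, ties
broken by the lowest sensor id ("first in the list"); its own max − min is
the amplitude. Brood day: max ≥ 32.0 °C **and** amplitude ≤ 2.0 °C, both
inclusive. Onset: first day of the earliest run of ≥ 3 strictly
consecutive brood days — a missing calendar day breaks a run. Death:
"did not recover" is not defined operationally in the source description,
so the package uses a terminal-run rule — the first day of the trailing
run in which the selected sensor's daily max stays ≤ 17.0 °C through the
last observed day; any recovery cancels the call. Death is evaluated on
the warmest sensor (the conservative reading of "temperatures inside the
colony"); a config switch could move this to raw samples, which is left
out of scope. When onset and death coincide on a day, death wins (the
colony is treated as too weak). The brood-day proportion counts only days
strictly before death.

## Statistical stage

All event-time models are Cox proportional-hazards fits with Efron tie
handling (weeks produce heavy tying). Term tests are sequential (type-I,
R `anova`-style) analyses of deviance: terms enter in the documented
order, and each term's statistic is twice the partial-log-likelihood gain
over the previous model, referred to χ² with the term's df. The null
partial likelihood is computed in closed form (at β = 0 each of d tied
events at a time with risk-set size n contributes −log(n − j)).

Shared log-normal frailty per grouping unit (flying arena; swarm origin)
is approximated by the documented fallback: a plain partial-likelihood fit
with cluster-robust variance on the unit, recorded in every result's
notes. Point estimates are unchanged by this substitution; only variances
differ from a penalized frailty fit.

The flowering-proportion model is a binomial GLM on per-pot counts with
χ² deviance tests; the brood-day proportion model is quasibinomial — the
same binomial fit with dispersion estimated from the full model's Pearson
χ²/df, and term F tests on scaled deviance drops. The height model is a
linear mixed model (random arena intercept, darkness excluded because
etiolation inflates heights); term tests use ML likelihood-ratio χ²
because the backend provides no Satterthwaite small-sample F — this is the
documented fallback, noted in each result, and an OLS fallback handles
singular random effects. The weight model is OLS of ln|mean daily change|
per colony × brood status with sequential ANOVA F tests; zero mean changes
(log undefined) are excluded with a note.

The cross-species models convert colony onset days to the plants' weekly
scale by week = ⌈day/7⌉ and fit species, photoperiod and their interaction
within one temperature regime. The grouping structure behind the robust
variance is configurable (separate units per species — arena for plants,
swarm-origin class for colonies — or one shared factor), since the
published description is ambiguous.

Estimated marginal means are cell means on a balanced grid; pairwise
contrasts use the studentized-range (Tukey) family-wise adjustment with
the model's residual df (asymptotic df for Cox scales). For a balanced
one-way layout this reproduces the classical Tukey HSD, which is the
family-wise error oracle in the tests. Printed proportion summaries use
the sample sd (n − 1) over per-pot proportions, rounded half away from
zero to two decimals. α = 0.05 throughout.

## Calibration and problem sizes

The test suite checks, with fixed seeds, that each model's headline term
rejects at ~5 % under null data. Null calibration runs at moderately
pooled sizes — 96 event rows for the Cox models, 64 heights, 48 colonies
for the quasibinomial model, 300–500 replicates per model — chosen so the
χ²/F reference distributions are trustworthy while the whole calibration
block stays a few minutes; at the study's own n = 24 the onset model's
likelihood-ratio tests are expected to be slightly liberal, which is a
property of the method, not of this implementation. Detector round-trips
use 16-week profiles and 100 colonies per condition. Effect-recovery
checks use n = 500 with a true hazard ratio of 2.

## Known limitations

* No chamber thermal inertia, LED spectral model, or varroa/feeding
  covariates; these are out of scope by design.
* The published per-cell statistics (the χ², F and p values of the study's
  tables) require the original chamber recordings, which are deliberately
  not a dependency; the pipeline reproduces the *structure* of those
  analyses and is validated on synthetic data with known truth.
* The synthetic telemetry's sensor gradient and death decay are
  plausibility stand-ins, so passing round-trip tests demonstrates
  correctness of the detection rules, not field performance on real hives.
* The frailty and Satterthwaite substitutions above mean variance-based
  quantities (standard errors, contrast p-values) can differ from
  `coxme`/`lmerTest` output on the same data; likelihood-ratio statistics
  and point estimates agree (the R `survival::coxph` cross-check in the
  test suite verifies the Cox stage to ~1e-3).
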