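# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Snow detection from soil loggers

A logger buried ~4 cm under a snow-covered plot reads ~0 °C with no diurnal
cycle; once the plot melts out, radiative heating drives a daily swing well
above 1 °C. The classifier marks a day *snow-covered* when

* diurnal range (daily max − min) < `range_threshold` (default 1.0 °C), and
* |daily mean| ≤ `zero_band` (default 1.0 °C).

The published rule is the diurnal-range condition; the zero band is our
addition, needed because a stable warm (or cold) spell can have a small
range without being snow — and because real sensors are noisy around 0 °C.
Both knobs are exposed on the CLI.

"Consistent snow cover" is operationalised as runs of at least `min_run`
consecutive snow days (default 5): a run-length guard suppresses single-day
artifacts, and the value is deliberately conservative for mid-winter
snowpacks that last months. Appearance is the first day of the first
qualifying run; disappearance the last day of the last run, so a brief melt
followed by re-burial extends the season rather than ending it (the
disappearance date is defined as the *latest* day with consistent cover).
Up to 2 consecutive days without logger data inside a run inherit the run's
class; longer gaps break the run and are recorded in the notes. Duration
counts days inside qualifying runs, bridged gap days included. Days with
fewer than 4 of the 8 expected 3-hourly samples are flagged low-coverage
but still classified.

With the generator's noiseless loggers the detector recovers the true melt
day exactly; at 0.2 °C sensor noise and 5 °C amplitude it is within ±1 day
in ≥95% of replicates (both are tested).

## SDD imputation

Roughly a fifth of plot-years lack a measured snow-disappearance date
(sensor failure or loss). Missing values are filled from an additive
fixed-effects least-squares model

    SDD(site, year) = intercept + site_effect + year_effect + calibration

with sum-to-zero constraints on both effect sets (fitted via OLS with Sum
contrasts). Additivity is a necessity, not just a preference: with at most
one observation per plot-year, a site × year interaction is saturated and
could never predict an unobserved cell. Year enters as a categorical code
rather than a linear trend, so no monotone climate signal is presumed.
`calibration` is an optional additive day offset (default 0) mirroring the
calibration column of the snow-season table; its derivation is treated as a
given input. The model refuses disconnected designs, levels with no
observed data, and extrapolation to unseen sites or years; observed SDD
values are never overwritten. A parallel field-calibration campaign that
the original workflow could draw on is external data and is not
reproduced; the additive model is the package's imputation method.

## Flowering curves

Flowering observations for one species × plot × year are binary
presence/absence reports indexed by day of year. The curve is a Gaussian
bump

    p(t) = μ · exp(−(t − ρ)² / (2 δ²)),   δ > 0, 0 < μ ≤ 1,

the canonical unimodal form with exactly the three parameters the data
products carry: maximum probability μ attained at the peak day ρ, with
width δ in days. The exact functional form used upstream is published only
in an external repository; the parameterisation here matches the recorded
(Peak, Duration, Maximum) columns, and the probability function is a single
shared definition used by both the generator and the estimator, so
recovery tests are meaningful. If a different unimodal form is ever
required, `flowering_probability` is the one place to change it.

Estimation is bounded multi-start maximum likelihood (L-BFGS-B, 10 starts)
on the Bernoulli negative log-likelihood with probabilities clipped to
[1e-10, 1 − 1e-10]. Bounds: δ ∈ [1, 60] days, μ ∈ [0.01, 1], ρ within the
observed season ± 15 days — subalpine flowering seasons are short, and the
ρ margin prevents flat-likelihood escapes. The first start uses the median
positive date (ρ), the positive fraction (μ), and half the positive date
range, floored at 5 days (δ); the rest are jittered copies, seeded and
deterministic. Cells with fewer than 5 reports or no positive report raise
an explicit unfittable error with a reason — the table driver skips and
records them rather than emitting default parameters. Degenerate
all-positive data fit with μ pinned at its upper bound; `at_bound()`
exposes this.

*Flowering richness* on day *t* counts species whose maximum-over-plots
fitted probability reaches a threshold — by default half that species'
fitted maximum (0.5 μ̂), overridable to an absolute probability; "in
flower" has no canonical definition for this display, so the half-maximum
convention is ours.

Curves are fitted per transect; both-trail species are not pooled across
transects.

Note on observation error: curves fitted to reports made by imperfect
observers estimate the *observed* flowering probability. A volunteer
false-positive rate of 1 − specificity adds a baseline the Gaussian bump
cannot represent, which biases δ̂ up and μ̂ down on error-laden data. The
parameter-recovery tests therefore draw Bernoulli data directly from the
curve (the estimator's own model), while full-pipeline runs on synthetic
data with realistic error rates are reported as-is.

## Observer agreement

Scientist and volunteer reports pair at the (date, transect, plot, species)
grain — the finest grain at which both a reference and a test assessment
exist, and the one required to stratify metrics by species and phenophase.
Each volunteer record pairs against the single scientist reference for the
key; multiple scientist records collapse by any-presence OR (configurable
to first-record). Each pair contributes four binary comparisons, one per
phenophase. Accuracy, sensitivity, and specificity follow the standard 2×2
definitions with the scientist as reference; the printed form of the
sensitivity denominator in the source material contains a typo
(SY.SY for SY.CY) and is implemented as TP/(TP + FN), the formula's own
verbal definition. Undefined metrics (zero denominators) propagate as
missing — a 3-pair stratum must not report perfect scores. The reference
terminology does not presume scientists are infallible: with an imperfect
reference the estimated rates are attenuated toward the reference's own
error, which is why the inversion tests use an error-free reference
configuration.

## Summaries

A *trail report* is a datasheet-level unit — one distinct (date, transect,
observer party) submission — not a species row. Mean inter-report intervals
use gaps between consecutive *distinct* report dates (two same-day parties
contribute one date), with the growing season bounded by the first and last
report of the trail-year; the statistic is undefined (with a reason) below
two distinct dates. A role filter allows scientist-only or volunteer-only
intervals.

## The synthetic generator

Defaults mirror the field design: 14 plots per transect (28 total) across
the published elevation ranges; Reflection Lakes monitored 2013–2019 and
Glacier Basin from 2015 (trail establishment history); season window DOY
120–280; ~4 volunteer submissions per week drawn with a weekend bias plus
a weekly fixed-weekday scientist walk (total within the 3–9/week band);
each plot hosting 3 of its trail's focal species, which yields ~56,000
observation rows over the default years — the tens-of-thousands magnitude
of the real archive; 20% of plot-years losing their logger; volunteer
sensitivity 0.75 and specificity 0.90 against 0.98/0.98 scientists
(ballpark figures consistent with the published agreement levels). True
SDD increases with elevation (3.5 d / 100 m) plus year effects (sd 6 d) and
plot noise (sd 3 d).

Phenophase schedules are keyed to snowmelt: peak flowering sits a
species-specific offset (3–9 weeks) after the plot's SDD, the flowering
window spans ρ ± 2δ, buds lead flowering by 10 days, fruit and seed lag by
δ and 2δ, and all onsets clamp at the SDD (preserving the bud ≤ flower ≤
fruit ≤ seed onset order). The latent flowering state on a given day is a
single Bernoulli draw from the true curve shared by every observer that
day; bud/fruit/seed are deterministic window indicators. Recorded values
flip through each role's sensitivity/specificity, per species and
phenophase. Snow codes derive from the SDD (covered → partial within 7
days of melt → free). Abundance ranks are populated only for 2013–2015
report years; herbivory flags only from 2017, as in the archive.

What the generator does **not** emulate: within-plot abundance behind a
presence record (observation is plot-level presence, matching the recorded
grain), spatial autocorrelation beyond the elevation–SDD trend,
species interactions, observer learning or skill heterogeneity, and
herbivory dynamics (iid Bernoulli flags). Passing tests therefore
demonstrate correctness of the estimators under the stated observation
model, not robustness to every structure real field data may carry.

Determinism: one `numpy` generator seeded from the study seed drives every
draw in a fixed order, so identical configuration + seed reproduce
byte-identical output files.

## Numerical and degenerate-input conventions

* DOY: January 1 = 1; leap years via calendar arithmetic.
* Date dialects: day-first in the report table, month-first in the
  snow-season table — enforced per file, tested to disagree on purpose.
* Missing cells read from `NA` or empty tokens, write as `NA`; snow code
  0.5 round-trips as the literal token `0.5`. Herbivory missing values are
  preserved at the IO layer (downstream analyses may treat them as absence,
  but only explicitly).
* Violation reports pinpoint row and field; non-strict parsing excludes
  offending rows and never fabricates values; strict mode raises on the
  first violation.
* An entirely snow-free logger yields zero duration and missing dates; an
  all-snow series yields a "no melt observed" note with missing SDD.

## Problem sizes

The test suite and the acceptance script size their simulation experiments
so each check is statistically meaningful while the whole suite stays
quick: 100 noiseless and 200 noisy logger replicates for snow detection,
60–100 replicates per sample size (n = 20/60/180) for curve recovery, a
20×20×20 likelihood grid for the optimizer oracle, 200 replicates for
SDD-model unbiasedness, and an agreement study sized to hold well over 200
pairs per phenophase stratum.
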