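# Methods

## The open birth interval

The open birth interval is the time elapsed since a woman's most recent
live birth, observed at a survey interview.  Formally it is the backward
recurrence time of the birth process: pick a woman at a random
inspection instant and measure back to her last event.  Tabulated over a
cross-section of married women of reproductive age, the distribution of
women by interval year descends steeply and regularly from the first
year to the twentieth, and its level and slope track a population's
fertility closely.  This package implements that analysis end to end:
tabulation from survey-style microdata, decomposition by age and parity,
four-family curve fitting, cross-survey correlation and trend analyses,
the stationary-renewal connection to closed intervals, and a
microsimulator that generates microdata with the structure the analysis
assumes.

## Tabulation rules

Eligibility follows the survey convention: currently married women aged
15–49 who are mothers (parity ≥ 1) or currently pregnant.  Interval year
k covers months [12(k−1), 12k) since the last birth, with dates held as
century-month codes (CMC, months since January 1900) so all interval
arithmetic is exact integer work.  Two rules matter:

* **Pregnant women are assigned to interval year 1** regardless of the
  date of their last birth (including pregnant nulliparae, who otherwise
  have no open interval).  They are about to re-enter the first-year
  group and resemble it in composition.
* **Intervals of 20 or more years are excluded** and percentages are
  renormalized over bins 1–20, so every distribution sums to 100.  The
  raw exclusion count is kept in a diagnostics field.  (An alternative —
  a residual 20+ bin — would break the sums-to-100 convention of the
  reference curves; we renormalize and expose the count.)

Exclusions are enumerable (not married / age out of range / nulliparous
not pregnant / 20+ years) and each record maps to exactly one bin or one
reason, which makes the tabulation a partition and order-invariant.

In the parity decomposition the displayed categories are parities 1–5
and 6+ (top-coded for display only); per-interval mean parity always
uses the true, un-top-coded parity.  Pregnant nulliparae belong to no
displayed parity category and are counted in a note.  The age–parity
table, unlike the interval tabulation, includes parity-0 women: it
describes the whole married population of each age group.

`mean_parity_from_printed_row` reconstructs a printed table row's mean
as Σ k·p_k/100 with the open-ended 6+ column coded at k = 6; it is exact
for rows whose 6+ cell is zero and a lower bound otherwise.

## The power model and its comparators

The central summary of a distribution is the two-parameter power curve

    y(x) = a · x^(−b),   x = 1 … 20,

with y the proportion of women in interval year x.  `a` is the level at
x = 1 — essentially the share of women pregnant or within a year of a
birth — and `b` the magnitude of the downward slope.  Both rise with
fertility, and across surveys they move almost in lockstep (a Pearson
correlation near −0.98 between a and signed b on the packaged
75-country panel), because a curve that starts high must fall fast to
keep its sum at 100%.

Estimation is ordinary least squares after the classical linearizing
transform: log y on log x for the power family, log y on x for the
exponential, and direct OLS for the logarithmic (c + d·ln x) and
degree-2 polynomial families.  This is the spreadsheet-trendline
convention and the plausible provenance of published parameter tables;
it is deliberately not a weighted or multinomial-likelihood fit.  Zero
bins are dropped from log fits and counted in a diagnostics field.

Because the transform changes the error metric, every fit reports two
R² values: `r2_transformed` in its own fitting space (what a
spreadsheet trendline prints) and `r2_original` = 1 − SS_res/SS_tot on
the proportion scale over all 20 bins.  The model comparison ranks by
`r2_original` so all four families are judged in the same space, with
ties broken toward fewer parameters.  The two can diverge materially on
steep high-fertility curves, where the log-space fit tolerates a large
absolute overshoot of the first bin; published panels show the same
signature (fitted levels above the observed first-bin share in
high-fertility countries), which is one reason to read their R² columns
as fitting-space values.  A degenerate all-equal distribution is handled
explicitly: a perfect constant fit scores R² = 1 under the 0/0
convention, so no family fails.

The polynomial degree is fixed at 2 — the smallest nonlinear polynomial
and the spreadsheet default — since the comparison targets two-or-three
parameter summaries, not flexible smoothers.

## Reference tables and cleaning rules

Two printed tables ship with the package (plain CSV, provenance comment,
sha256 integrity check on load):

* the Colombia parity-within-age table (7 age groups × 6 surveys,
  1990–2015, with printed row means), and
* the 75-country panel of power-model parameters (a, b), TFR, GFR and
  reported fit R².

Panel cleaning: parenthesized b values denote negative slopes
(accounting convention), so magnitudes are negated on load.  Three rows
— Benin 2017-18, Guinea 2018, Haiti 2016-17 — print b magnitudes below
0.2 against a levels above 0.4.  That combination contradicts the
level–slope coupling above (every other row with a > 0.4 has |b| > 1.2)
and is exactly the signature of a dropped decimal digit; these are
treated as decimal-shift misprints, multiplied by 10 before negation,
and flagged `b_corrected`.  The correction is on by default and can be
disabled (`correct_b=False`, CLI `--no-b-correction`).  The panel's R²
column cannot be re-derived without the underlying microdata and is
carried as metadata only.

A caveat found while validating the panel: recomputed from the printed
rows, the level a correlates with TFR at 0.886 and with GFR at 0.871 —
close to, but below, the 0.91 sometimes quoted for both parameters.
The slope b does exceed it (−0.925, −0.915).  The package reports the
recomputed values; the corresponding acceptance check is left failing
rather than relaxed.

## Fertility measures

TFR and GFR are computed from full birth histories over a reference
window before the interview (default 36 months — recent enough to be a
period measure, wide enough to tame small-sample noise; the window is a
parameter).  TFR sums age-specific rates over the seven 5-year groups
15–49 times 5; GFR is births per 1,000 woman-years at ages 15–44.  A
woman's own birth date is placed at the midpoint of her reported
completed age (interview CMC − 12·age − 6).  Rates use the whole
simulated population, married or not — the conventional denominators —
while interval tabulation restricts to married women; mean CEB is the
mean parity of women 15–49.

## Renewal theory

For a stationary renewal process with closed-interval survivor function
S and mean μ, the open interval (backward recurrence time) has density
f_B(t) = S(t)/μ; conversely μ = 1/f_B(0) and S(t) = f_B(t)/f_B(0).
`DurationDistribution` holds densities on a uniform grid (default
resolution 0.25–1 month, capped at 360 months, matching CMC-dated
data); integrals use the trapezoid rule, which keeps the survivor-
integral mean exact to ~10⁻⁴ relative for smooth densities.  The
inversion differentiates Ŝ numerically (central differences), clips
negative values, and refuses densities that increase anywhere — an
increasing backward-recurrence density is impossible under stationarity.

The stationary sampler draws n independent renewal processes and
inspects each at a time drawn uniformly on [T₀, 2T₀] with T₀ = 50 mean
durations — long after process start, independent of the process's own
randomness, so the inspected spell is length-biased exactly as in a
cross-sectional survey (and deterministic closed intervals still yield
a uniform backward time).  Validation reports the Kolmogorov–Smirnov
distance between sampled backward times and the analytic f_B; at
n = 50,000 the observed distances are well under 0.02, and a wide
tolerance (0.15) applies below n = 10,000 where KS noise ~ n^(−1/2)
dominates.

Casting an *observed* open-interval distribution into this machinery is
gated behind an explicit `--assume-stationary` flag: absent a stable
population the inversion's fertility implications are unreliable, and
the package does not attempt fertility estimation from real
open-interval data.

## The microsimulator

`simulate_survey` generates the kind of microdata the analysis assumes,
one woman at a time in monthly steps: marriage (age drawn from a
discretized-normal distribution over 15–35), conception as a Bernoulli
trial at `monthly_fecundability` × an age-profile multiplier × a
per-woman frailty × (1 − effectiveness·using), gestation (9 months),
postpartum infecundability (lactational amenorrhea), and an absorbing
sterility onset drawn from a piecewise-constant per-month hazard by
5-year age group.  Contraceptive behaviour is parity-driven: a woman
who has reached her desired parity (drawn from a configurable
distribution over 0–12) uses contraception if she belongs to the using
fraction, and imperfect effectiveness generates unplanned births — the
mechanism behind the long upper tail of parity distributions in
low-desired-fertility regimes.

Three choices deserve explanation:

* **Stable state by construction.**  Every woman's full reproductive
  life is simulated under fixed rates before a single census is taken,
  so the sampled cross-section is automatically in the stable state;
  the census date is exchangeable with any other (tested).  Ages at
  the census follow a stable-population density ∝ exp(−r·age), which
  reproduces the thinning of older cohorts that shapes the long tail.
* **Heterogeneous fecundability.**  A gamma-distributed per-woman
  multiplier (mean 1, CV configurable, default 0.6) spreads conception
  risk across couples.  Without it the simulated curve is close to a
  single-rate renewal profile — too thin in the tail and visibly
  non-power; with it, together with early sterility onsets, the
  tabulated curve acquires the smooth power-like decline observed in
  real surveys.
* **Counter-based per-woman streams.**  Randomness comes from one
  master seed with per-woman streams spawned by counter, so enlarging
  the cohort extends it without reshuffling earlier women, and equal
  seeds give byte-identical output.

Mortality is not modelled (neither female nor spousal); spousal absence
is available only as a constant exposure-reduction factor.  Both act on
real curves, so passing tests here says nothing about their effects.

Two presets bracket the observed range: a Niger-like natural-fertility
regime (early marriage, 13 months postpartum infecundability, desired
family size ~8.5, 22% contraceptive prevalence, 3% growth; simulated
TFR ≈ 7, first-interval share ≈ 47%) and a Colombia-like transitional
regime (marriage ~24, two-child norm, 95% prevalence at 99.5%
effectiveness; TFR ≈ 2, first-interval share ≈ 20%).  Presets are
qualitative regimes, not calibrated reproductions of any country's
printed distribution.  `regime_ladder` interpolates all behavioural
parameters jointly across 12 steps, spanning TFR ≈ 1.5–7.5, and is the
basis of the cross-regime panel checks (level a rising and signed b
falling with TFR, TFR against mean open interval strongly negative).

What the generator does *not* emulate: union dissolution and
remarriage, abortion, survey weights and non-response, age heaping and
date misreporting, multi-stage cluster sampling, migration, and period
shocks (all surveys are censuses of a stationary regime).  Checks that
pass on simulated data therefore validate the pipeline's arithmetic
and the qualitative comparative statics, not any claim about a
particular country's data quality.

## Problem sizes and determinism

Default experiment sizes — 20,000-woman preset surveys, 4,000-woman
cohorts per ladder regime, 200 fit-recovery replicates at n = 10,000,
50,000 renewal inspections — were chosen so each check's Monte-Carlo
noise sits well inside its assertion margin while a full run of the
suite and the acceptance script completes in about a minute.  All
stochastic paths take explicit seeds; the acceptance script derives
per-component seeds from a single `--seed` via `SeedSequence.spawn`.

## Known limitations

* Log-space OLS is a biased estimator of (a, b) under multinomial
  sampling at small n; bias at the default n = 10,000 is ≈ 0.005 on b
  (measured), immaterial here but worth knowing before use at n ≪ 1,000.
* The renewal inversion amplifies noise at t = 0 (μ̂ = 1/f_B(0)); it is
  intended for smooth model densities, not raw histograms.
* TFR from 36-month windows on simulated cohorts carries sampling
  noise of a few percent at n = 4,000; rank-based cross-regime checks
  absorb this, point comparisons would not.
* The survey CSV schema reserves no weight column semantics yet;
  weighted tabulation is future work.
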