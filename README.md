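# openinterval

Analysis of the **open birth interval** — the time since a woman's most
recent live birth, observed at a survey interview — for demographers and
reproductive-health researchers working with DHS-style microdata.

Across surveys, the distribution of married women aged 15–49 by open
interval year x = 1 … 20 descends steeply and regularly, and is summarized
remarkably well by a two-parameter power curve

```
y(x) = a · x^(−b)
```

where y is the proportion of women in interval year x, *a* is the level of
the curve at x = 1 (the share pregnant or within a year of a birth) and *b*
the magnitude of its downward slope.  Both parameters rise with fertility
and move almost in lockstep with each other.  The open interval is also the
**backward recurrence time** of the birth process: in a stationary
population its density is f_B(t) = S(t)/μ, with S the closed-interval
survivor function and μ the mean closed interval, so either distribution
determines the other.

The package provides:

* **Tabulation** of open-interval distributions from a documented survey
  CSV schema (CMC dates, DHS recode mapping), with the standard inclusion
  rules: pregnant women in the first interval year, exclusion beyond the
  20th year, married women 15–49.
* **Decompositions** by age group and parity, age–parity tables with true
  (un-top-coded) mean parity, and printed-row mean reconstruction.
* **Curve fitting** of the power model and three comparators
  (exponential, logarithmic, quadratic) with R² reported both in the
  fitting space and on the original proportion scale.
* **Fertility measures** (TFR, GFR, mean CEB) from birth histories.
* **Panel analyses**: parameter–fertility correlations, fertility vs mean
  interval, within-country trend slopes across repeat surveys; a packaged
  75-country reference panel of (a, b, TFR, GFR) and a Colombia
  parity-by-age table ship as fixtures with documented cleaning rules.
* **Renewal theory**: closed ↔ open interval conversion and a stationary
  renewal sampler for validation.
* A **microsimulator** of reproductive histories (fecundability with
  gamma frailty, gestation, lactational infecundability, parity-driven
  contraception, sterility onset, stable-population age structure) that
  generates survey-style microdata under configurable fertility regimes,
  from a Niger-like natural-fertility preset to a Colombia-like
  transitional preset.

See `docs/methods.md` for the model details, simulator assumptions and
design choices.

## Worked example

Simulate a high-fertility survey, tabulate it, and fit the four families:

```python
import openinterval as oi

cfg = oi.high_fertility_preset(cohort_size=20_000, seed=7).config
records = oi.simulate_survey(cfg)

dist = oi.tabulate_distribution(records, "high_fertility")
print(dist.percentages[:5].round(1))   # [47.  17.   8.1  5.2  3.7]

comparison = oi.compare_models(dist)
best = comparison.best
print(best.family, round(best.params["a"], 3), round(best.params["b"], 3),
      round(best.r2_original, 3))      # power 0.535 1.609 0.979

print(round(oi.mean_open_interval(records), 2))   # 2.82  (years)
print(round(oi.compute_tfr(records), 2))          # 6.76
```

Forty-seven percent of eligible women are pregnant or within a year of a
birth — the signature of a natural-fertility regime — and the power curve
wins the comparison with level a = 0.53 and slope b = 1.61, right in the
range seen in high-fertility country panels.  The same survey under the
`colombia` preset starts near 20% and fits a ≈ 0.12, b ≈ 0.45.

The packaged 75-country panel reproduces the tight level–slope coupling:

```python
panel = oi.load_country_panel()
r, r2 = oi.pearson(panel["a"], panel["b"])
print(round(r, 3))                     # -0.979
```

The same stages are scriptable from the shell:

```
openinterval simulate --preset niger --n 20000 --seed 7 --out survey.csv
openinterval tabulate --in survey.csv --out dist.csv
openinterval fit --in dist.csv --out fits.csv
openinterval panel --fixture --out panel_results/
openinterval demo --out demo_output
```

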