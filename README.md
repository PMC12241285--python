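# voltiscan

Detecting voltinism shifts — changes in the number of insect generations per
year — and the temperature cues behind them, from long-term light-trap catch
series and daily temperature records.

Many temperate Lepidoptera are facultatively bivoltine: a second adult
generation emerges within the year only when conditions permit direct pupal
development instead of overwintering diapause. A standardized light trap
operated over decades yields daily species-level catch counts in which a
second flight period appears as a second seasonal cluster of capture dates.
`voltiscan` turns such a series, plus a daily minimum/maximum temperature
record, into an end-to-end analysis:

1. **Flight-period classification.** Pooled capture weeks are modelled as a
   two-component equal-variance Gaussian mixture on the week-of-year axis,
   f(w) = π·N(w; μ₁, σ²) + (1−π)·N(w; μ₂, σ²), fitted by EM. A year is
   called bivoltine only if at least one of its observations has posterior
   probability > 0.999 of belonging to the late component — a conservative
   rule that keeps long early-period tails from being mistaken for a second
   generation.
2. **Critical-window scan.** For every candidate window on a season grid
   (start days from 23 September of the previous year through 31 July,
   durations 5–60 days; 17,472 windows) and each of daily minimum, maximum
   and mean temperature, a binomial GLM
   logit P(second flight period in year t) = β₀ + β₁·x̄(window, t)
   is fitted to the per-year window means. Windows are ranked by McFadden's
   pseudo-R² = 1 − ℓ/ℓ₀; effect sizes are reported as odds ratios e^{β₁}
   with profile-likelihood 95% intervals.
3. **Validation.** Decade-subset sensitivity (re-scanning all contiguous
   decade subsets and meta-regressing the winning window's effect size,
   midpoint and duration on subset start and length) and block K-fold
   cross-validation (5-year blocks held out in turn) scored by accuracy and
   by raw discrepancy Σ(predicted − observed).
4. **Thresholds and trends.** The temperature at which the fitted
   probability of a second flight period reaches 0.5 (T\* = −β₀/β₁), the OLS
   warming trend of the window mean over the full record, and the calendar
   year at which the trend line crosses T\*.
5. **Abundance.** An NB2 negative-binomial GLM (variance μ + μ²/k, log
   link) of first-flight-period counts on the previous flight period's
   size, the previous year's voltinism, their interaction, and overwinter
   (October–June) mean temperature, pruned by top-down likelihood-ratio
   selection — a test for density dependence and for any demographic cost
   of the extra generation.

A synthetic-data generator with a known hidden window, logistic temperature
response and planted density dependence makes every stage verifiable by
parameter recovery without any data download.

## Input formats

CSV with a header row and ISO-8601 dates:

* catches: `date,count` (one row per trap date; zero counts allowed);
* temperature: `date,tmin,tmax[,tmean]` — a missing daily mean is estimated
  as (tmin + tmax)/2. Calendar gaps are permitted, but any window mean that
  touches a gap is reported invalid rather than averaged over fewer days.

## Worked example

```bash
voltiscan simulate --out demo            # synthetic bundle, default seed
voltiscan all --catches demo/catches.csv --temps demo/temperature.csv --out demo/run
```

or in Python:

```python
from voltiscan import VoltinismStudy, PipelineConfig
from voltiscan.synthetic import SyntheticConfig, generate_dataset

temps, catches, truth = generate_dataset(SyntheticConfig(seed=1))
results = VoltinismStudy(catches, temps, PipelineConfig(seed=1)).fit()
print(results.summary())
```

which prints (abridged):

```
Two-component equal-variance normal mixture (n=5138)
  early mean  mu1 = 22.43 weeks
  late mean   mu2 = 33.33 weeks
  shared sd  sigma = 1.92 weeks
Years with two flight periods: 30 of 56 classified
Best windows by variable:
  min temperature, window start=240 duration=45 d: pseudo-R2=0.492, OR=33.32 [7.49, 281.73], n=56
  max temperature, window start=246 duration=57 d: pseudo-R2=0.180, OR=3.13 [1.65, 6.88], n=56
  mean temperature, window start=246 duration=43 d: pseudo-R2=0.355, OR=10.92 [3.71, 47.51], n=56
Overall winner: min temperature, 45-day window 21 May-04 Jul
Threshold temperature (p=0.5): 9.70 degC
Window min temperature trend: 0.0209 degC/yr (t_(1,54)=3.38, p=0.0014)
Trend crosses threshold in: 1991
K-fold CV: 12 folds, 56 predictions, accuracy=0.821, raw discrepancy=+0
```

Reading this: the two flight periods sit at weeks 22.4 and 33.3 (the
generator's truth); daily *minimum* temperature wins the scan (it is the
planted driver), with the recovered window centred within two weeks of the
hidden 1 June–19 July window; each extra degree in the window multiplies
the odds of a second flight period ~33-fold; the half-probability threshold
is 9.7 °C (truth: 10.0 °C); and held-out prediction is 82% accurate with no
systematic bias. The abundance selection (also printed) retains the
previous-generation term with a positive coefficient — the planted positive
density dependence.

Every stage also writes CSV/JSON artifacts (`classification.csv`,
`scan_grid.csv`, `best_window.json`, `trends.json`, `cv_predictions.csv`,
`abundance_table.csv`, `selection.json`, `summary.json`) to the output
directory.

## Analysing real trap data

Point the CLI at your own CSVs and supply the site's exclusion ledger
(years lost to equipment failure) in a YAML config:

```yaml
catches_path: trap_catches.csv
temps_path: temperature_grid_cell.csv
failure_years: [1973, 1993, 2017]
year_range: [1968, 2023]
```

```bash
voltiscan all --config site.yaml --out results/
```
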