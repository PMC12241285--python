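# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, the numerical choices, and what the synthetic tests do
and do not establish about real data.

## Calendar and season grid

All leap-year handling is by raw day-of-year (DOY). The season over which
candidate windows are enumerated runs from DOY 266 of the previous calendar
year (23 September, 22 September in leap years) through DOY 212 of the
focal year (31 July, 30 July in leap years): the interval between the
latest plausible end of a second flight period and the earliest date one
can begin. That yields 312 admissible window start days (season days
0–311) in every season, leap or not; windows extend up to 60 days forward,
so the grid carries 372 slots. One consequence of a 365-slot DOY grid: 31
December of a leap year (DOY 366) has no slot of its own — it is the single
date per leap cycle that cannot round-trip through the grid — and it never
enters a window mean. Window starts are *anchored* at season days 0–311 and
may overhang past 31 July; a config flag (`require_end_within_season`)
optionally restricts window ends to the season.

Weeks are ceiling(DOY/7), weeks 1–53. No standard week scheme reproduces a
"week 30 ending 30 July" exactly (ceiling(DOY/7) puts the end of week 30 at
29 July in non-leap years); the ceiling convention was adopted as the most
common one in this analysis ecosystem, and the one-day discrepancy is
immaterial at week resolution.

Daily mean temperature, where not supplied, is the midpoint (tmin+tmax)/2 —
the standard estimator when only extremes are recorded. `estimate_daily_mean`
never overwrites a supplied mean and is idempotent.

## Flight-period mixture

Pooled capture weeks (one observation per individual by default; a
per-capture-date mode exists) are modelled as a two-component normal
mixture with a **shared** variance, fitted by EM. The equal-variance
constraint is imposed in the M-step by pooling the within-component sum of
squares. Initialization is deterministic (means at the 25th/75th
percentiles) plus nine randomized restarts from a fixed seed; the best
final log-likelihood wins and components are ordered μ₁ < μ₂, which makes
the fit invariant to label permutation. Convergence: relative
log-likelihood change < 1e-9, cap 1000 iterations; the trace is kept so the
EM monotonicity invariant can be asserted. The number of components is
fixed at two; the summary reports 2ΔLL against a single-normal fit as the
support measure rather than searching over k.

A year is bivoltine iff some observation has posterior late-component
probability strictly greater than the threshold (default 0.999). The
strictness and the high cutoff are deliberate: with long-tailed flight
periods a lax rule would misread stragglers as a second generation. A year
with catches only in the late cluster is classified bivoltine by the same
rule with no special case. Equipment-failure years (user-supplied ledger)
are excluded; zero-catch years without recorded failure are excluded from
classification but re-enter the abundance stage as zero counts.

## GLM kernel

The binomial (logit) GLM is fitted by Newton/IRLS with step-halving, to
relative log-likelihood change < 1e-10 within 100 iterations; the converged
solution satisfies the score equations to ‖X'(y−p̂)‖∞ < 1e-8. Complete
separation for a single covariate is detected combinatorially (the classes
occupy disjoint covariate ranges after sorting) and also flagged whenever a
standardized coefficient exceeds 30; separated fits are returned flagged,
with the confidence interval suppressed.

Odds-ratio intervals are **profile-likelihood**, not Wald: the bounds are
exp of the slope values where the profile deviance rises by the χ²₁(0.95)
quantile, found by bracketed root-finding on a profile computed by 1-D
Newton over the intercept (covariate centred internally for conditioning).
Profile intervals are asymmetric for strong effects, which matters here
because winning windows often have large odds ratios. Pseudo-R² is
McFadden's 1 − ℓ/ℓ₀ (other variants exist; McFadden is the conventional
headline value and the ranking statistic of the scan).

The scan uses a vectorized damped-Newton solver fitting all windows'
two-parameter GLMs simultaneously (steps capped at 5 standardized units per
iteration, 60 iterations); the winning window is refitted with the scalar
IRLS path and the two agree to ~1e-6. Window means come from cumulative
sums over the season axis, so a full 3-variable scan is O(days + windows)
per year and runs in about a second for 56 years.

Linear trends use closed-form OLS with the classical t statistic (df =
n − 2). The NB2 negative-binomial GLM (log link, variance μ + μ²/k) is
fitted by joint ML over coefficients and dispersion via statsmodels'
discrete-model implementation behind the package's own interface; k > 1e4
is flagged as effectively Poisson. Likelihood-ratio tests require equal row
counts and nested term sets, with df equal to the fixed-effect parameter
difference.

## Window scan and selection

One GLM per (start, duration) pair, start-major enumeration, excluded years
dropped listwise. The arg-max by pseudo-R² breaks exact ties by shorter
duration, then earlier start; across variables, ties resolve in the order
min, max, mean. Windows touching any temperature gap are invalid rather
than silently averaged.

## Trends and threshold

The presence-on-year GLM uses uncentred calendar year (centring would change
only the intercept, and no intercept-based quantity is reported from that
fit). The warming trend is OLS of the winning window's annual means on year
over **all** study years with temperature coverage — no moth-data
exclusions, since only the temperature record is involved. The crossing
year solves trend(year) = T\* and reports the first calendar year at or
above the crossing (ceiling); a crossing before the record's first year is
flagged rather than hidden.

## Validation

Decade subsets are built on the ordered classified years: consecutive
blocks of ten (a shorter leftover joins the last block), with the default
scheme enumerating **all** contiguous decade runs — 15 subsets for a
5-decade span — and a nested trim-from-one-end scheme (9 subsets) available
by config. The exhaustive scheme is the default because its meta-regression
has 12 residual degrees of freedom under the two-predictor model (subset
start and duration, both in decades), matching the design this analysis is
patterned on. Subsets whose years share one status are skipped with a
warning.

Cross-validation holds out consecutive blocks (default 5 years) in turn,
re-runs the full scan on the remaining years only, and predicts the
held-out years from the winning model; fitted probability ≥ 0.5 maps to
presence (the boundary case goes to presence, closing the gap the >0.5 /
<0.5 convention leaves open). Accuracy is the matched fraction; raw
discrepancy is Σ(predicted − observed) = #FP − #FN, a signed bias measure.
Validation contains no randomness and is bit-reproducible.

## Abundance model

The response is the count of individuals hard-assigned to the first flight
period (posterior arg-max; under equal variances and weights the boundary
is the midpoint of the two means, ties to the first period — the
catch-to-period rule is the package's own choice, as is treating a
zero-catch previous year as univoltine with lag 0). The lag covariate is
the previous year's second-period count when that year was bivoltine,
otherwise its total. Rows are absent for the first study year (no lag),
equipment-failure years, and the year after each failure; zero-catch years
enter as zeros. The overwinter covariate is the mean daily mean from 1
October to 30 June (273 days, 274 across a leap February).

Selection is backward elimination from
`count ~ prev_count * prev_voltinism + oct_jun_mean` by LRT at α = 0.05,
interaction first (main effects are not droppable while their interaction
is present); the least significant droppable term is removed each step.
Terms with 0.05 ≤ p < 0.1 are excluded from the final model but flagged
"marginal" in the trace, so a marginally significant covariate remains
visible in the report rather than silently vanishing.

## Synthetic generator

The generator emulates exactly the structure the analysis assumes, with
defaults chosen as the study conditions:

| parameter | default | rationale |
|---|---|---|
| year_range | 1968–2023 | 56 seasons |
| true window | season days 251–299 | 1 Jun – 19 Jul, 49 days |
| logistic slope β | 2.7875 /°C | odds ratio ≈ 16.2 per °C |
| logistic intercept α | −27.875 | half-probability threshold 10.0 °C |
| flight-period means | 22.4 / 33.3 weeks | early June / mid August |
| shared week SD | 1.9 | overlapping but separable clusters |
| warming trend | 0.026 °C/yr | ~1.4 °C over the record |
| annual-mean tmin / amplitude | 4.6 / 5.5 °C | west-Scotland-like seasonal cycle placing the June–July window mean near the 10 °C threshold mid-record |
| AR(1) φ / noise SD | 0.7 / 2.0 °C | weather-spell persistence; makes overlapping windows' means correlate, so window identification is genuinely hard |
| diurnal offset / its AR(1) SD | 7.0 / 2.5 °C | cloud-cover-like variability: tmax (and hence tmean) are noisier proxies of the tmin cue |
| base abundance | 15 /generation/year | realistic single-site trap counts |
| density coefficient | 0.03 /individual | ~3% multiplicative effect per individual |
| density ceiling | 60 | the lag covariate saturates above this, keeping an exponential-link feedback bounded over 56 years |
| second-generation scaling | 0.8 | late broods somewhat smaller |
| NB2 dispersion k | 5 | moderate overdispersion |

Daily tmin is sinusoid + linear trend + AR(1) noise; tmax adds a positive
AR(1) diurnal offset (floored at 0.5 °C); tmean is the midpoint. Brood
sizes are NB2 with log-mean linear in the (ceiling-clipped) previous
generation size; the second generation occurs with probability
logistic(α + β·mean tmin over the hidden window) and its size depends on
the same year's first brood. Capture weeks are normal around the component
means, rounded, and placed uniformly within the week (the analysis is
week-resolution, so sub-week placement is immaterial). All draws derive
from one seed and are byte-reproducible; a truth record logs every latent
draw.

What the generator does **not** emulate: detection/trapping efficiency and
weather-dependent trap performance, photoperiod interactions, spatial
structure, within-season phenology shifts (fixed μ₁, μ₂ across years), and
gridded-temperature-product extraction error. Passing recovery tests therefore demonstrates the
pipeline's correctness under its own assumptions — not that those
assumptions hold for any particular trap series.

## Problem sizes in the tests

Recovery tests use 50-season series, 20 seeds, and the full 17,472-window
enumeration (3 variables); the profile-interval coverage check uses 500
replicates at n = 200. Steep-response recovery tests set β = 6 (a strong,
cleanly identified cue); the defaults (β ≈ 2.8) are used everywhere else.
These sizes mirror the scale of the motivating kind of study while keeping
the whole suite fast on a single core.

## Known limitations

* The per-window GLM ranking ignores multiplicity: the scan's best
  pseudo-R² is an optimized statistic, which is precisely why the subset
  and cross-validation scrutiny stages exist.
* Separated window fits (possible under steep synthetic responses) have
  divergent coefficients; they are flagged, their CIs suppressed, and the
  serialized odds ratio capped, but their pseudo-R² still participates in
  ranking, as any exhaustive scan implicitly does.
* The NB2 dispersion is assumed common across years; no autocorrelated or
  state-space population dynamics beyond the single lag term.
* The abundance response depends on the posterior hard assignment of
  individuals to flight periods; near the component boundary this is a
  coin-flip region, though with well-separated means few observations land
  there.
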