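"""Headline derivations: presence trend, temperature threshold, warming rate.

Three quantities summarize the voltinism shift once the critical window is
known: the odds ratio per year for the presence of a second flight period,
the window temperature at which that probability reaches one half
(T* = -b0/b1 of the presence-on-temperature GLM), and the linear warming
trend of the window mean over the full temperature record, whose crossing of
T* dates the transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import DailySeries
from .flight_periods import YearVoltinism
from .stats_core import (
    FitError,
    GlmFit,
    LmFit,
    OddsRatio,
    fit_binomial_glm,
    fit_linear_model,
    profile_odds_ratio,
)
from .window_scan import WindowSpec, window_mean

__all__ = ["ThresholdResult", "fit_presence_trend", "threshold_temperature",
           "window_temperature_trend", "crossing_year"]


@dataclass(frozen=True)
class ThresholdResult:
    """Half-probability temperature and the year the warming trend reaches it."""

    threshold_temp: float
    crossing_year: int
    before_record: bool = False   # crossing precedes the first observed year


def fit_presence_trend(status: Sequence[YearVoltinism]) -> tuple[GlmFit, OddsRatio]:
    """Binomial GLM of second-flight-period presence on calendar year."""
    rows = [(v.year, 1.0 if v.status == "two" else 0.0)
            for v in status if v.status in ("one", "two")]
    if not rows:
        raise FitError("no classified years")
    years = np.array([r[0] for r in rows], dtype=float)
    y = np.array([r[1] for r in rows])
    if y.min() == y.max():
        raise FitError("all classified years share one status")
    if min(y.sum(), len(y) - y.sum()) < 2:
        raise FitError("need at least 2 years of each status")
    fit = fit_binomial_glm(y, years, names=("year",))
    orr = profile_odds_ratio(fit)
    return fit, orr


def threshold_temperature(fit: GlmFit) -> float:
    """Covariate value at which the fitted probability equals 0.5: -b0/b1."""
    if fit.n_params != 2:
        raise FitError("threshold requires a single-covariate fit")
    b0, b1 = fit.params
    if b1 == 0:
        raise FitError("zero slope: threshold undefined")
    return float(-b0 / b1)


def window_temperature_trend(temps: DailySeries, window: WindowSpec,
                             years: Sequence[int],
                             variable: str = "min") -> LmFit:
    """OLS of annual window means on year over the full temperature record.

    Unlike the presence models, no moth-data exclusions apply here: every
    year with full window coverage in the temperature series participates.
    """
    means = [window_mean(temps, variable, window, sy) for sy in years]
    return fit_linear_model(means, list(years))


def crossing_year(trend: LmFit, threshold: float,
                  first_year: int | None = None) -> ThresholdResult:
    """First calendar year at which the fitted trend reaches the threshold."""
    if trend.slope <= 0:
        raise FitError("non-positive trend slope: no crossing")
    exact = (threshold - trend.intercept) / trend.slope
    year = math.ceil(exact - 1e-9)
    before = first_year is not None and year < first_year
    return ThresholdResult(threshold_temp=float(threshold),
                           crossing_year=int(year), before_record=before)
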