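"""Synthetic light-trap and temperature data with a known critical window.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage can be tested by parameter recovery:

* daily minimum temperature = seasonal sinusoid + linear warming trend +
  AR(1) noise (autocorrelated, so means of overlapping windows correlate as
  in real weather — this is what makes window identification nontrivial);
  daily maximum adds a positive diurnal offset with its own AR(1) noise;
* two Gaussian flight-period clusters on the week-of-year axis;
* a Bernoulli second generation whose log-odds are linear in the mean daily
  minimum temperature over a hidden season window;
* negative-binomial (NB2) brood sizes with positive lag-1 density dependence
  (saturating above a ceiling so the series stays bounded over decades).

A :class:`TruthRecord` logs every latent draw for later comparison.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_io import (
    CatchSeries,
    DailySeries,
    SeasonIndex,
    estimate_daily_mean,
    season_date,
)

__all__ = ["SyntheticConfig", "TruthRecord", "generate_temperature",
           "generate_catches", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters; defaults are the study conditions.

    The hidden window defaults to season days 251..299 (1 June - 19 July), a
    49-day window; the logistic slope corresponds to an odds ratio of ~16 per
    degree Celsius with a 10 degC half-probability threshold; flight-period
    means/SD sit at 22.4 / 33.3 / 1.9 weeks; warming is 0.026 degC/yr.
    """

    year_range: tuple[int, int] = (1968, 2023)
    true_window: tuple[int, int] = (251, 49)     # (start season_day, duration)
    logistic_alpha: float = -27.875
    logistic_beta: float = 2.7875                # log-odds per degC
    mu1: float = 22.4                            # early flight-period mean (weeks)
    mu2: float = 33.3                            # late flight-period mean (weeks)
    sigma: float = 1.9                           # shared week SD
    warming_slope: float = 0.026                 # degC per year on tmin
    base_tmin: float = 4.6                       # annual-mean daily minimum, degC
    seasonal_amplitude: float = 5.5              # degC
    peak_doy: int = 199                          # warmest day of year (mid July)
    ar_coefficient: float = 0.7                  # AR(1) coefficient of daily noise
    noise_sd: float = 2.0                        # stationary SD of tmin noise, degC
    diurnal_offset: float = 7.0                  # mean tmax - tmin, degC
    diurnal_noise_sd: float = 2.5                # AR(1) stationary SD of the offset
    base_abundance: float = 15.0                 # expected first-generation count
    density_coefficient: float = 0.03            # log-mean per individual (lag 1)
    density_ceiling: float = 60.0                # lag covariate saturates here
    second_gen_fraction: float = 0.8             # late-brood baseline scaling
    dispersion: float = 5.0                      # NB2 size k
    seed: int = 0

    def __post_init__(self):
        if not (5 <= self.true_window[1] <= 60):
            raise ValueError("true window duration must lie in 5..60 days")
        if self.sigma <= 0 or self.dispersion <= 0:
            raise ValueError("sigma and dispersion must be positive")
        if not self.mu1 < self.mu2:
            raise ValueError("mu1 must be below mu2")
        if not (0 <= self.ar_coefficient < 1):
            raise ValueError("ar_coefficient must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["year_range"] = list(self.year_range)
        d["true_window"] = list(self.true_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "year_range" in d:
            d["year_range"] = tuple(d["year_range"])
        if "true_window" in d:
            d["true_window"] = tuple(d["true_window"])
        return cls(**d)

    @property
    def threshold_temperature(self) -> float:
        """Temperature at which the second-generation probability is 0.5."""
        return -self.logistic_alpha / self.logistic_beta


@dataclass
class TruthRecord:
    """Ground truth behind one synthetic data set."""

    config: SyntheticConfig
    years: list[int]
    second_generation: dict[int, bool]     # Bernoulli draw actually taken
    window_mean_tmin: dict[int, float]     # mean tmin over the true window
    second_gen_probability: dict[int, float]
    first_gen_size: dict[int, int]
    second_gen_size: dict[int, int]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "years": self.years,
            "second_generation": {str(y): bool(v) for y, v in self.second_generation.items()},
            "window_mean_tmin": {str(y): v for y, v in self.window_mean_tmin.items()},
            "second_gen_probability": {str(y): v for y, v in self.second_gen_probability.items()},
            "first_gen_size": {str(y): int(v) for y, v in self.first_gen_size.items()},
            "second_gen_size": {str(y): int(v) for y, v in self.second_gen_size.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _ar1(rng: np.random.Generator, n: int, phi: float, stationary_sd: float) -> np.ndarray:
    """AR(1) series with the given stationary standard deviation."""
    if stationary_sd == 0:
        return np.zeros(n)
    innov_sd = stationary_sd * math.sqrt(max(1.0 - phi * phi, 1e-12))
    e = np.empty(n)
    e[0] = rng.normal(0.0, stationary_sd)
    shocks = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + shocks[t]
    return e


def generate_temperature(config: SyntheticConfig) -> DailySeries:
    """Daily tmin/tmax/tmean from one year before the study start onward.

    The extra leading year provides the autumn half of the first season and
    the October onset of the first overwinter covariate.
    """
    y0, y1 = config.year_range
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    start = dt.date(y0 - 1, 1, 1)
    end = dt.date(y1, 12, 31)
    n = (end - start).days + 1
    dates = [start + dt.timedelta(days=i) for i in range(n)]
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    years = np.array([d.year for d in dates], dtype=float)
    seasonal = config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - config.peak_doy) / 365.25)
    trend = config.warming_slope * (years - y0)
    noise = _ar1(rng, n, config.ar_coefficient, config.noise_sd)
    tmin = config.base_tmin + seasonal + trend + noise
    offset = np.maximum(
        config.diurnal_offset + _ar1(rng, n, config.ar_coefficient,
                                     config.diurnal_noise_sd), 0.5)
    tmax = tmin + offset
    frame = pd.DataFrame({"date": dates, "tmin": tmin, "tmax": tmax})
    return estimate_daily_mean(DailySeries(frame))


def _true_window_mean(temps: DailySeries, config: SyntheticConfig, year: int) -> float:
    start, duration = config.true_window
    tmins = temps.value_map("min")
    total = 0.0
    for s in range(start, start + duration):
        d = season_date(SeasonIndex(year, s))
        if d not in tmins:
            raise ValueError(f"temperature series missing {d} inside the true window")
        total += tmins[d]
    return total / duration


def _week_to_date(rng: np.random.Generator, year: int, week: int) -> dt.date:
    """Uniform random day within the drawn week (analysis is week-resolution)."""
    doy = (week - 1) * 7 + int(rng.integers(1, 8))
    doy = min(doy, 365)
    return dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)


def generate_catches(config: SyntheticConfig,
                     temps: DailySeries) -> tuple[CatchSeries, TruthRecord]:
    """Draw yearly broods and individual capture dates given the temperatures.

    First-generation size is NB2 with log-mean = log(base_abundance) +
    density_coefficient * min(previous generation size, density_ceiling); a
    second generation occurs with probability
    logistic(alpha + beta * mean tmin over the hidden window) and its size is
    scaled by ``second_gen_fraction`` with density dependence on the same
    year's first generation.  Capture weeks are normal around mu1 / mu2.
    """
    y0, y1 = config.year_range
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    k = config.dispersion

    def draw_nb(mean: float) -> int:
        p = k / (k + mean)
        return int(rng.negative_binomial(k, p))

    def clipped_logmean(base: float, prev: float) -> float:
        return math.log(base) + config.density_coefficient * min(
            prev, config.density_ceiling)

    counts: dict[dt.date, int] = {}
    truth = TruthRecord(config=config, years=list(range(y0, y1 + 1)),
                        second_generation={}, window_mean_tmin={},
                        second_gen_probability={}, first_gen_size={},
                        second_gen_size={})
    prev_size = config.base_abundance
    for year in range(y0, y1 + 1):
        n1 = draw_nb(math.exp(clipped_logmean(config.base_abundance, prev_size)))
        wmean = _true_window_mean(temps, config, year)
        with np.errstate(over="ignore"):
            p2 = float(expit(config.logistic_alpha + config.logistic_beta * wmean))
        bivoltine = bool(rng.random() < p2)
        n2 = 0
        if bivoltine:
            base2 = config.base_abundance * config.second_gen_fraction
            n2 = draw_nb(math.exp(clipped_logmean(base2, n1)))
        for size, mu in ((n1, config.mu1), (n2, config.mu2)):
            if size == 0:
                continue
            weeks = np.clip(np.rint(rng.normal(mu, config.sigma, size=size)),
                            1, 53).astype(int)
            for w in weeks:
                d = _week_to_date(rng, year, int(w))
                counts[d] = counts.get(d, 0) + 1
        truth.second_generation[year] = bivoltine
        truth.window_mean_tmin[year] = wmean
        truth.second_gen_probability[year] = p2
        truth.first_gen_size[year] = n1
        truth.second_gen_size[year] = n2
        prev_size = n2 if bivoltine else n1
    frame = pd.DataFrame(sorted(counts.items()), columns=["date", "count"])
    if frame.empty:
        frame = pd.DataFrame({"date": pd.Series(dtype="datetime64[ns]"),
                              "count": pd.Series(dtype=int)})
    return CatchSeries(frame), truth


def generate_dataset(config: SyntheticConfig) -> tuple[DailySeries, CatchSeries, TruthRecord]:
    """Temperature plus catches plus ground truth, reproducible from the seed."""
    temps = generate_temperature(config)
    catches, truth = generate_catches(config, temps)
    return temps, catches, truth
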