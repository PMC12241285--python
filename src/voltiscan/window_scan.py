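"""Exhaustive sliding-window search for the critical temperature cue.

Candidate windows live on the season grid (start day 0..311, i.e. 23 Sep of
the previous year through 31 Jul; durations 5..60 days).  For each window
and temperature variable the per-year window mean is computed, a binomial
GLM of second-flight-period presence on that mean is fitted, and windows are
ranked by McFadden pseudo-R-squared.  Cumulative sums over the season axis
make the 17,472-window scan O(days + windows) per year, and a vectorized
Newton solver fits all windows' GLMs simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import (
    DailySeries,
    N_SEASON_START_DAYS,
    SeasonIndex,
    season_date,
)
from .flight_periods import YearVoltinism
from .stats_core import (
    GlmFit,
    OddsRatio,
    batch_logistic,
    fit_binomial_glm,
    mcfadden_r2,
    profile_odds_ratio,
    FitError,
)

__all__ = ["WindowSpec", "WindowFit", "ScanGrid", "SeasonTemperatureMatrix",
           "enumerate_windows", "window_mean", "scan_variable", "best_overall",
           "VARIABLE_ORDER"]

MIN_DURATION = 5
MAX_DURATION = 60
GRID_LEN = N_SEASON_START_DAYS + MAX_DURATION  # window overhang past 31 Jul
VARIABLE_ORDER = ("min", "max", "mean")


class ScanError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class WindowSpec:
    """A candidate window: start day on the season grid and duration in days."""

    start: int
    duration: int

    def __post_init__(self):
        if not (0 <= self.start <= N_SEASON_START_DAYS - 1):
            raise ValueError(f"start {self.start} outside 0..{N_SEASON_START_DAYS - 1}")
        if not (MIN_DURATION <= self.duration <= MAX_DURATION):
            raise ValueError(f"duration {self.duration} outside "
                             f"{MIN_DURATION}..{MAX_DURATION}")

    @property
    def midpoint(self) -> float:
        return self.start + (self.duration - 1) / 2.0

    def dates(self, season_year: int):
        """(first day, last day) as calendar dates for the given season."""
        first = season_date(SeasonIndex(season_year, self.start))
        last = season_date(SeasonIndex(season_year, self.start + self.duration - 1))
        return first, last


def enumerate_windows(require_end_within_season: bool = False) -> list[WindowSpec]:
    """All (start, duration) pairs, start-major then duration.

    With the optional constraint, windows ending past the last admissible
    season day are dropped.
    """
    out = []
    for start in range(N_SEASON_START_DAYS):
        for duration in range(MIN_DURATION, MAX_DURATION + 1):
            if require_end_within_season and start + duration - 1 > N_SEASON_START_DAYS - 1:
                continue
            out.append(WindowSpec(start, duration))
    return out


class SeasonTemperatureMatrix:
    """Per-season daily values of one temperature variable on the season grid,
    with cumulative sums for O(1) window means.  Missing days are tracked so
    a window touching a gap is reported invalid, never silently averaged."""

    def __init__(self, temps: DailySeries, variable: str,
                 season_years: Sequence[int]):
        if variable not in VARIABLE_ORDER:
            raise ScanError(f"unknown variable {variable!r}")
        vm = temps.value_map(variable)
        self.variable = variable
        self.season_years = list(season_years)
        n = len(self.season_years)
        M = np.full((n, GRID_LEN), np.nan)
        for i, sy in enumerate(self.season_years):
            for s in range(GRID_LEN):
                M[i, s] = vm.get(season_date(SeasonIndex(sy, s)), np.nan)
        self.values = M
        ok = ~np.isnan(M)
        z = np.zeros((n, 1))
        self._csum = np.concatenate([z, np.cumsum(np.where(ok, M, 0.0), axis=1)], axis=1)
        self._ccnt = np.concatenate([z, np.cumsum(ok.astype(float), axis=1)], axis=1)

    def window_means(self, starts: np.ndarray, durations: np.ndarray) -> np.ndarray:
        """(n_seasons, n_windows) matrix of window means; NaN where any day
        of the window is missing."""
        starts = np.asarray(starts)
        durations = np.asarray(durations)
        ends = starts + durations
        sums = self._csum[:, ends] - self._csum[:, starts]
        cnts = self._ccnt[:, ends] - self._ccnt[:, starts]
        with np.errstate(invalid="ignore"):
            return np.where(cnts == durations, sums / durations, np.nan)


def window_mean(temps: DailySeries, variable: str, window: WindowSpec,
                season_year: int) -> float:
    """Mean of the chosen daily variable over one window of one season."""
    vm = temps.value_map(variable)
    total = 0.0
    for s in range(window.start, window.start + window.duration):
        d = season_date(SeasonIndex(season_year, s))
        if d not in vm or np.isnan(vm[d]):
            raise ScanError(f"window invalid: temperature missing on {d}")
        total += vm[d]
    return total / window.duration


@dataclass
class WindowFit:
    """The presence GLM for one window of one variable."""

    variable: str
    window: WindowSpec
    glm: GlmFit
    odds_ratio: OddsRatio | None     # None when separation suppresses the CI
    pseudo_r2: float
    n_years: int

    def summary(self) -> str:
        orr = (f"OR={self.odds_ratio.point:.2f} "
               f"[{self.odds_ratio.lower:.2f}, {self.odds_ratio.upper:.2f}]"
               if self.odds_ratio else "OR CI suppressed (separation)")
        return (f"{self.variable} temperature, window start={self.window.start} "
                f"duration={self.window.duration} d: pseudo-R2={self.pseudo_r2:.3f}, "
                f"{orr}, n={self.n_years}")


@dataclass
class ScanGrid:
    """Full enumeration result for one temperature variable."""

    variable: str
    windows: list[WindowSpec]
    pseudo_r2: np.ndarray
    loglik: np.ndarray
    best: WindowFit
    years: list[int]

    def as_records(self) -> list[dict]:
        out = []
        for w, r2, ll in zip(self.windows, self.pseudo_r2, self.loglik):
            out.append({"variable": self.variable, "start": w.start,
                        "duration": w.duration, "pseudo_r2": float(r2),
                        "loglik": float(ll)})
        return out


def _classified(status: Sequence[YearVoltinism]) -> tuple[list[int], np.ndarray]:
    years = [v.year for v in status if v.status in ("one", "two")]
    y = np.array([1.0 if v.status == "two" else 0.0
                  for v in status if v.status in ("one", "two")])
    return years, y


def scan_variable(temps: DailySeries, status: Sequence[YearVoltinism],
                  variable: str, windows: list[WindowSpec] | None = None,
                  compute_ci: bool = True) -> ScanGrid:
    """Fit one presence GLM per enumerated window; excluded years dropped
    listwise; arg-max by pseudo-R2 with ties broken (shorter, then earlier)."""
    years, y = _classified(status)
    if len(years) < 10:
        raise ScanError(f"need at least 10 classified years, have {len(years)}")
    if y.min() == y.max():
        raise ScanError("all classified years share one status: scan degenerate")
    if windows is None:
        windows = enumerate_windows()
    starts = np.array([w.start for w in windows])
    durs = np.array([w.duration for w in windows])
    mat = SeasonTemperatureMatrix(temps, variable, years)
    means = mat.window_means(starts, durs)          # (n_years, W)
    valid = ~np.isnan(means).any(axis=0)
    if not valid.any():
        raise ScanError("no window has full temperature coverage")
    covs = means[:, valid].T                        # (W_valid, n_years)
    fit = batch_logistic(y, covs)
    ll0 = _null_ll(y)
    r2 = np.full(len(windows), np.nan)
    ll = np.full(len(windows), np.nan)
    ll[valid] = fit["loglik"]
    r2[valid] = 1.0 - fit["loglik"] / ll0
    best_idx = _argmax_with_ties(r2, durs, starts)
    best_window = windows[best_idx]
    x_best = means[:, best_idx]
    glm = fit_binomial_glm(y, x_best, names=(f"{variable}_window_mean",))
    orr = None
    if compute_ci and not glm.separation:
        try:
            orr = profile_odds_ratio(glm)
        except FitError:
            orr = None
    best = WindowFit(variable=variable, window=best_window, glm=glm,
                     odds_ratio=orr, pseudo_r2=mcfadden_r2(glm),
                     n_years=len(years))
    return ScanGrid(variable=variable, windows=windows, pseudo_r2=r2,
                    loglik=ll, best=best, years=years)


def _null_ll(y: np.ndarray) -> float:
    p = y.mean()
    return float(len(y) * (p * np.log(p) + (1 - p) * np.log(1 - p)))


def _argmax_with_ties(r2: np.ndarray, durations: np.ndarray,
                      starts: np.ndarray) -> int:
    finite = np.isfinite(r2)
    top = np.nanmax(r2[finite])
    tied = np.flatnonzero(finite & (r2 == top))
    if len(tied) == 1:
        return int(tied[0])
    order = sorted(tied, key=lambda i: (durations[i], starts[i]))
    return int(order[0])


def best_overall(grids: dict[str, ScanGrid] | Sequence[ScanGrid]) -> WindowFit:
    """The winning window across variables, ties resolved in canonical
    variable order (min, max, mean)."""
    if isinstance(grids, dict):
        grid_map = grids
    else:
        grid_map = {g.variable: g for g in grids}
    best = None
    for var in VARIABLE_ORDER:
        if var not in grid_map:
            continue
        cand = grid_map[var].best
        if best is None or cand.pseudo_r2 > best.pseudo_r2:
            best = cand
    if best is None:
        raise ScanError("no grids supplied")
    return best
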