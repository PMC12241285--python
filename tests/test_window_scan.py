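import datetime as dt

import numpy as np
import pandas as pd
import pytest

from voltiscan.data_io import DailySeries, SeasonIndex, season_date
from voltiscan.flight_periods import YearVoltinism
from voltiscan.window_scan import (
    ScanError,
    SeasonTemperatureMatrix,
    WindowSpec,
    best_overall,
    enumerate_windows,
    scan_variable,
    window_mean,
)


def _series(year0, year1, fn):
    start = dt.date(year0, 1, 1)
    end = dt.date(year1, 12, 31)
    dates = [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]
    vals = np.array([fn(d) for d in dates], dtype=float)
    return DailySeries(pd.DataFrame({"date": dates, "tmin": vals,
                                     "tmax": vals + 8.0,
                                     "tmean": vals + 4.0}))


class TestEnumerateWindows:
    def test_total_count(self):
        # 312 start days x 56 durations
        assert len(enumerate_windows()) == 312 * 56 == 17472

    def test_first_element_is_range_minima(self):
        first = enumerate_windows()[0]
        assert (first.start, first.duration) == (0, 5)

    def test_contains_the_june_window(self):
        # 49 days from 1 June (season day 251) through 19 July
        w = WindowSpec(251, 49)
        assert w in enumerate_windows()
        assert season_date(SeasonIndex(2001, 251)) == dt.date(2001, 6, 1)
        assert season_date(SeasonIndex(2001, 299)) == dt.date(2001, 7, 19)

    def test_end_constraint(self):
        constrained = enumerate_windows(require_end_within_season=True)
        assert all(w.start + w.duration - 1 <= 311 for w in constrained)
        assert len(constrained) < 17472

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            WindowSpec(312, 10)
        with pytest.raises(ValueError):
            WindowSpec(0, 4)


class TestWindowMean:
    def test_constant_series(self):
        temps = _series(1999, 2001, lambda d: 7.0)
        assert window_mean(temps, "min", WindowSpec(100, 30), 2001) == pytest.approx(7.0)

    def test_linear_ramp_equals_midpoint(self):
        base = dt.date(1999, 1, 1)
        temps = _series(1999, 2001, lambda d: (d - base).days * 0.01)
        w = WindowSpec(120, 31)
        mid_date = season_date(SeasonIndex(2001, 135))
        assert window_mean(temps, "min", w, 2001) == pytest.approx(
            (mid_date - base).days * 0.01)

    def test_matrix_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        temps = _series(1999, 2002, lambda d: float(rng.normal()))
        years = [2000, 2001, 2002]
        windows = [WindowSpec(0, 5), WindowSpec(99, 10), WindowSpec(251, 49),
                   WindowSpec(311, 60)]
        mat = SeasonTemperatureMatrix(temps, "min", years)
        means = mat.window_means(np.array([w.start for w in windows]),
                                 np.array([w.duration for w in windows]))
        vm = temps.value_map("min")
        for j, w in enumerate(windows):
            for i, sy in enumerate(years):
                naive = np.mean([vm[season_date(SeasonIndex(sy, s))]
                                 for s in range(w.start, w.start + w.duration)])
                assert means[i, j] == pytest.approx(naive, abs=1e-12)

    def test_split_consistency(self):
        rng = np.random.default_rng(1)
        temps = _series(1999, 2001, lambda d: float(rng.normal()))
        w = WindowSpec(150, 40)
        left = WindowSpec(150, 19)
        right = WindowSpec(169, 21)
        total = window_mean(temps, "mean", w, 2001)
        combined = (19 * window_mean(temps, "mean", left, 2001)
                    + 21 * window_mean(temps, "mean", right, 2001)) / 40
        assert total == pytest.approx(combined, abs=1e-12)

    def test_gap_raises_naming_date(self):
        temps = _series(1999, 2001, lambda d: 5.0)
        missing = season_date(SeasonIndex(2001, 260))
        frame = temps.frame[temps.frame["date"] != missing]
        with pytest.raises(ScanError, match=str(missing)):
            window_mean(DailySeries(frame), "min", WindowSpec(251, 20), 2001)

    def test_leap_dec31_never_enters_a_window(self):
        # 2000 is a leap year: DOY 366 has no grid slot, so removing
        # 31 Dec 2000 from the series leaves every window mean intact
        temps = _series(1999, 2001, lambda d: 3.0)
        frame = temps.frame[temps.frame["date"] != dt.date(2000, 12, 31)]
        assert window_mean(DailySeries(frame), "min",
                           WindowSpec(95, 10), 2001) == pytest.approx(3.0)


def _status(yearvals):
    return [YearVoltinism(y, "two" if v else "one", 0.5, "none")
            for y, v in yearvals]


@pytest.fixture(scope="module")
def planted():
    """20 seasons whose status is driven by the mean over season days
    200..229 of tmin, with heavy noise elsewhere."""
    rng = np.random.default_rng(5)
    years = list(range(1991, 2011))
    perturb = {y: rng.normal(0, 2.0) for y in years}

    def fn(d):
        return 5.0 + perturb.get(d.year, 0.0) + float(rng.normal(0, 0.3))

    temps = _series(1989, 2011, fn)
    mat = SeasonTemperatureMatrix(temps, "min", years)
    means = mat.window_means(np.array([200]), np.array([30]))[:, 0]
    status = _status([(y, m > np.median(means) + 0.01 * rng.normal())
                      for y, m in zip(years, means)])
    return temps, status


class TestScanVariable:
    def test_grid_values_and_determinism(self, planted):
        temps, status = planted
        g1 = scan_variable(temps, status, "min", compute_ci=False)
        g2 = scan_variable(temps, status, "min", compute_ci=False)
        ok = np.isfinite(g1.pseudo_r2)
        assert np.all((g1.pseudo_r2[ok] >= -1e-9) & (g1.pseudo_r2[ok] < 1.0 + 1e-9))
        assert np.array_equal(g1.pseudo_r2, g2.pseudo_r2, equal_nan=True)
        assert g1.best.window == g2.best.window

    def test_argmax_attains_grid_maximum(self, planted):
        temps, status = planted
        g = scan_variable(temps, status, "min", compute_ci=False)
        assert g.best.pseudo_r2 == pytest.approx(np.nanmax(g.pseudo_r2), abs=1e-8)

    def test_permuted_labels_score_lower(self, planted):
        temps, status = planted
        real = scan_variable(temps, status, "min", compute_ci=False)
        rng = np.random.default_rng(17)
        labels = [v.status for v in status]
        rng.shuffle(labels)
        shuffled = [YearVoltinism(v.year, s, 0.5, "none")
                    for v, s in zip(status, labels)]
        try:
            perm = scan_variable(temps, shuffled, "min", compute_ci=False)
        except ScanError:
            return  # all-one-class shuffle: trivially lower
        assert np.nanmax(perm.pseudo_r2) < np.nanmax(real.pseudo_r2)

    def test_single_status_rejected(self, planted):
        temps, status = planted
        same = [YearVoltinism(v.year, "one", 0.1, "none") for v in status]
        with pytest.raises(ScanError, match="degenerate|one status"):
            scan_variable(temps, same, "min")

    def test_too_few_years_rejected(self, planted):
        temps, status = planted
        with pytest.raises(ScanError, match="10 classified"):
            scan_variable(temps, status[:8], "min")


class TestBestOverall:
    def test_tie_goes_to_min_variable(self, planted_grids=None):
        class G:
            def __init__(self, var, r2):
                self.variable = var
                self.best = type("B", (), {"pseudo_r2": r2, "variable": var})()

        grids = {v: G(v, 0.5) for v in ("min", "max", "mean")}
        assert best_overall(grids).variable == "min"

    def test_maximum_wins(self):
        class G:
            def __init__(self, var, r2):
                self.variable = var
                self.best = type("B", (), {"pseudo_r2": r2, "variable": var})()

        grids = {"min": G("min", 0.3), "max": G("max", 0.41), "mean": G("mean", 0.4)}
        assert best_overall(grids).variable == "max"
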