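"""Input tables and calendar utilities.

Two tabular inputs drive the whole analysis: a daily temperature series
(minimum / maximum, with the daily mean estimated as their midpoint where it
is not supplied) and a daily light-trap catch series for one species.  Both
are thin, validated wrappers around :class:`pandas.DataFrame`.

The calendar utilities define the coordinate system of the sliding-window
scan: a "season" runs from late September of one calendar year (the latest
possible date of a second flight period) through late July of the next (the
earliest date a second flight period can begin).  Dates are anchored by raw
day-of-year (DOY), which reproduces the leap-year behaviour of the study
design exactly: the season anchor is DOY 266 (23 Sep, or 22 Sep in a leap
year) and the last admissible window start is DOY 212 of the following year
(31 Jul, or 30 Jul in a leap year).  The season grid therefore has 365 slots;
31 December of a leap year (DOY 366) owns no slot and never enters a window.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailySeries",
    "CatchSeries",
    "SeasonIndex",
    "SEASON_ANCHOR_DOY",
    "SEASON_LAST_START_DOY",
    "N_SEASON_START_DAYS",
    "read_catch_csv",
    "read_temperature_csv",
    "estimate_daily_mean",
    "day_of_year",
    "week_of_year",
    "date_from_doy",
    "season_index",
    "season_date",
]

#: Day-of-year of the season anchor (23 Sep non-leap, 22 Sep leap).
SEASON_ANCHOR_DOY = 266
#: Day-of-year (in the season's second calendar year) of the last admissible
#: window start (31 Jul non-leap, 30 Jul leap).
SEASON_LAST_START_DOY = 212
#: Number of autumn slots on the season grid (DOY 266..365 of the prior year).
_AUTUMN_SLOTS = 365 - SEASON_ANCHOR_DOY + 1  # 100
#: Number of admissible window start days per season: season_day 0..311.
N_SEASON_START_DAYS = _AUTUMN_SLOTS + SEASON_LAST_START_DOY  # 312


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def day_of_year(date: dt.date) -> int:
    """1-based ordinal day within the calendar year."""
    return date.timetuple().tm_yday


def week_of_year(date: dt.date) -> int:
    """Week of year as ceiling(DOY / 7); weeks 1..53."""
    return math.ceil(day_of_year(date) / 7)


def date_from_doy(year: int, doy: int) -> dt.date:
    """Calendar date of the given raw day-of-year (1-based)."""
    return dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)


@dataclass(frozen=True)
class SeasonIndex:
    """Position of a date on the season grid.

    ``season_year`` is the calendar year whose (potential) second flight
    period the season leads up to; ``season_day`` counts from the anchor
    (0 = DOY 266 of ``season_year - 1``).
    """

    season_year: int
    season_day: int


def season_index(date: dt.date) -> SeasonIndex:
    """Map a calendar date onto the season grid.

    Dates on/after the anchor DOY belong to the following year's season.  In
    a leap year 31 December (DOY 366) shares slot 100 with 1 January; it is
    the single date per leap cycle that the 365-slot grid cannot give its own
    slot, and window means never include it.
    """
    doy = day_of_year(date)
    if doy >= SEASON_ANCHOR_DOY:
        return SeasonIndex(date.year + 1, min(doy, 366) - SEASON_ANCHOR_DOY)
    return SeasonIndex(date.year, (365 - SEASON_ANCHOR_DOY) + doy)


def season_date(index: SeasonIndex) -> dt.date:
    """Inverse of :func:`season_index` (slot -> its primary calendar date)."""
    if index.season_day < _AUTUMN_SLOTS:  # slots 0..99: DOY 266..365 of prior year
        return date_from_doy(index.season_year - 1, SEASON_ANCHOR_DOY + index.season_day)
    return date_from_doy(index.season_year, index.season_day - _AUTUMN_SLOTS + 1)


class DailySeries:
    """Daily minimum/maximum/mean temperature record (degrees Celsius).

    Invariants: dates strictly increasing with no duplicates, and
    tmin <= tmean <= tmax on every row.  Calendar gaps are permitted but are
    recorded in :attr:`gaps`; any window mean that touches a gap is reported
    as invalid rather than averaged over fewer days.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"date", "tmin", "tmax"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"temperature table missing columns: {sorted(missing)}")
        frame = frame.copy()
        frame["date"] = pd.to_datetime(frame["date"]).dt.date
        if frame["date"].duplicated().any():
            dups = [d.isoformat() for d in frame.loc[frame["date"].duplicated(), "date"]]
            raise ValidationError(f"duplicate temperature dates: {dups}")
        frame = frame.sort_values("date").reset_index(drop=True)
        bad = frame["tmin"] > frame["tmax"]
        if bad.any():
            bad_dates = [d.isoformat() for d in frame.loc[bad, "date"]]
            raise ValidationError(f"tmin > tmax on dates: {bad_dates}")
        if "tmean" not in frame.columns:
            frame["tmean"] = np.nan
        have = frame["tmean"].notna()
        out_of_band = have & (
            (frame["tmean"] < frame["tmin"]) | (frame["tmean"] > frame["tmax"])
        )
        if out_of_band.any():
            oob = [d.isoformat() for d in frame.loc[out_of_band, "date"]]
            raise ValidationError(f"tmean outside [tmin, tmax] on dates: {oob}")
        self.frame = frame[["date", "tmin", "tmax", "tmean"]]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> Sequence[dt.date]:
        return self.frame["date"].tolist()

    @property
    def gaps(self) -> list[dt.date]:
        """Calendar dates missing between the first and last record."""
        if len(self.frame) < 2:
            return []
        present = set(self.frame["date"])
        d0, d1 = self.frame["date"].iloc[0], self.frame["date"].iloc[-1]
        n = (d1 - d0).days
        return [
            d0 + dt.timedelta(days=i)
            for i in range(1, n)
            if d0 + dt.timedelta(days=i) not in present
        ]

    def value_map(self, variable: str) -> dict[dt.date, float]:
        """date -> daily value for ``variable`` in {'min', 'max', 'mean'}."""
        col = {"min": "tmin", "max": "tmax", "mean": "tmean"}[variable]
        return dict(zip(self.frame["date"], self.frame[col]))


class CatchSeries:
    """Dated non-negative capture counts of the focal species."""

    def __init__(self, frame: pd.DataFrame):
        required = {"date", "count"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"catch table missing columns: {sorted(missing)}")
        frame = frame.copy()
        frame["date"] = pd.to_datetime(frame["date"]).dt.date
        if frame["date"].duplicated().any():
            dups = sorted({d.isoformat() for d in frame.loc[frame["date"].duplicated(), "date"]})
            raise ValidationError(f"duplicate catch dates: {dups}")
        if (frame["count"] < 0).any():
            bad = [d.isoformat() for d in frame.loc[frame["count"] < 0, "date"]]
            raise ValidationError(f"negative counts on dates: {bad}")
        frac = frame["count"] != frame["count"].astype(int)
        if frac.any():
            frac_dates = [d.isoformat() for d in frame.loc[frac, "date"]]
            raise ValidationError(f"non-integer counts on dates: {frac_dates}")
        frame["count"] = frame["count"].astype(int)
        self.frame = frame.sort_values("date").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total(self) -> int:
        return int(self.frame["count"].sum())

    @property
    def years(self) -> list[int]:
        return sorted({d.year for d in self.frame["date"]})


def read_catch_csv(path: str | Path) -> CatchSeries:
    """Read a ``date,count`` CSV (header row, ISO-8601 dates)."""
    frame = pd.read_csv(path)
    if frame.empty and {"date", "count"} <= set(frame.columns):
        return CatchSeries(pd.DataFrame({"date": pd.Series(dtype="datetime64[ns]"),
                                         "count": pd.Series(dtype=int)}))
    try:
        frame["date"] = pd.to_datetime(frame["date"], format="ISO8601")
    except (ValueError, KeyError) as exc:
        raise ValidationError(f"{path}: unparseable date column: {exc}") from exc
    return CatchSeries(frame)


def read_temperature_csv(path: str | Path) -> DailySeries:
    """Read a ``date,tmin,tmax[,tmean]`` CSV and fill missing daily means."""
    frame = pd.read_csv(path)
    try:
        frame["date"] = pd.to_datetime(frame["date"], format="ISO8601")
    except (ValueError, KeyError) as exc:
        raise ValidationError(f"{path}: unparseable date column: {exc}") from exc
    return estimate_daily_mean(DailySeries(frame))


def estimate_daily_mean(series: DailySeries) -> DailySeries:
    """Fill absent daily means with (tmin + tmax) / 2; never overwrites.

    Idempotent: applying it twice equals applying it once.
    """
    frame = series.frame.copy()
    absent = frame["tmean"].isna()
    frame.loc[absent, "tmean"] = (frame.loc[absent, "tmin"] + frame.loc[absent, "tmax"]) / 2.0
    return DailySeries(frame)


def write_catch_csv(series: CatchSeries, path: str | Path) -> None:
    series.frame.to_csv(path, index=False)


def write_temperature_csv(series: DailySeries, path: str | Path) -> None:
    series.frame.to_csv(path, index=False)
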