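"""Model scrutiny: subset sensitivity of the window and block cross-validation.

Two checks probe the robustness of the chosen critical window.  First, the
scan is repeated on decade subsets of the classified years (all contiguous
decade-aligned runs by default) and the best window's effect size, midpoint
and duration are meta-regressed on subset start and duration — a drift in
these outputs would indicate a changing reaction norm.  Second, block K-fold
cross-validation re-runs the scan with 5-year blocks held out in turn and
scores the held-out predictions by classification accuracy and by raw
discrepancy (sum of predicted minus observed), a signed bias measure in
which false positives and false negatives cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import DailySeries
from .flight_periods import YearVoltinism
from .window_scan import ScanError, WindowSpec, scan_variable, window_mean

__all__ = ["Subset", "SubsetResult", "MetaRegression", "CVSummary",
           "enumerate_subsets", "subset_sensitivity", "kfold_blocks",
           "cross_validate"]

DECADE = 10
DEFAULT_BLOCK = 5


@dataclass(frozen=True)
class Subset:
    """A contiguous run of decades of the classified-year sequence."""

    start_year: int
    duration_years: int
    years: tuple[int, ...]
    start_decade: int       # decade offset of the first included decade
    n_decades: int


def _decades(years: Sequence[int]) -> list[list[int]]:
    ys = sorted(years)
    n_dec = len(ys) // DECADE
    if n_dec < 2:
        raise ValueError(f"need at least {2 * DECADE} years, have {len(ys)}")
    blocks = [ys[i * DECADE:(i + 1) * DECADE] for i in range(n_dec)]
    blocks[-1].extend(ys[n_dec * DECADE:])  # leftover years join the last decade
    return blocks


def enumerate_subsets(years: Sequence[int],
                      scheme: str = "exhaustive") -> list[Subset]:
    """Decade subsets of the ordered classified years.

    ``exhaustive`` (default): every contiguous run of whole decades —
    n(n+1)/2 subsets for n decades, the full span first (ordered by
    decreasing duration, then start).  ``nested``: the full span plus runs
    obtained by trimming whole decades from the end only or from the start
    only.
    """
    blocks = _decades(years)
    n = len(blocks)
    runs: list[tuple[int, int]] = []  # (first decade, n_decades)
    if scheme == "exhaustive":
        for length in range(n, 0, -1):
            for first in range(0, n - length + 1):
                runs.append((first, length))
    elif scheme == "nested":
        runs.append((0, n))
        for length in range(n - 1, 0, -1):
            runs.append((0, length))          # trimmed from the end
        for first in range(1, n):
            runs.append((first, n - first))   # trimmed from the start
    else:
        raise ValueError(f"unknown subset scheme {scheme!r}")
    out = []
    for first, length in runs:
        ys = [y for b in blocks[first:first + length] for y in b]
        out.append(Subset(start_year=ys[0], duration_years=ys[-1] - ys[0] + 1,
                          years=tuple(ys), start_decade=first, n_decades=length))
    return out


@dataclass(frozen=True)
class SubsetResult:
    """Best-window outputs for one decade subset."""

    subset_start_year: int
    subset_duration_years: int
    start_decade: int
    n_decades: int
    effect_size: float       # log-odds per degC
    odds_ratio: float        # exp(effect_size)
    midpoint: float          # season_day, start + (duration - 1)/2
    duration: int            # days


@dataclass(frozen=True)
class MetaRegression:
    """OLS of one subset output on (start decade, duration in decades)."""

    response: str
    coef_start: float
    coef_duration: float
    t_start: float
    t_duration: float
    p_start: float
    p_duration: float
    df_resid: int
    nobs: int


def _meta_ols(response_name: str, y: np.ndarray, start: np.ndarray,
              duration: np.ndarray) -> MetaRegression:
    import statsmodels.api as sm

    X = sm.add_constant(np.column_stack([start, duration]))
    res = sm.OLS(y, X).fit()
    return MetaRegression(
        response=response_name,
        coef_start=float(res.params[1]), coef_duration=float(res.params[2]),
        t_start=float(res.tvalues[1]), t_duration=float(res.tvalues[2]),
        p_start=float(res.pvalues[1]), p_duration=float(res.pvalues[2]),
        df_resid=int(res.df_resid), nobs=int(res.nobs),
    )


def subset_sensitivity(temps: DailySeries, status: Sequence[YearVoltinism],
                       variable: str, scheme: str = "exhaustive",
                       ) -> tuple[list[SubsetResult], dict[str, MetaRegression]]:
    """Re-scan each decade subset and meta-regress the best-window outputs.

    Predictors are in decades (start decade of the subset and its length in
    decades); single-status subsets are skipped with a warning.
    """
    classified = [v for v in status if v.status in ("one", "two")]
    years = [v.year for v in classified]
    results = []
    for sub in enumerate_subsets(years, scheme=scheme):
        sub_status = [v for v in status if v.year in set(sub.years)]
        try:
            grid = scan_variable(temps, sub_status, variable, compute_ci=False)
        except ScanError as exc:
            warnings.warn(f"subset {sub.start_year}+{sub.duration_years}y "
                          f"skipped: {exc}")
            continue
        best = grid.best
        results.append(SubsetResult(
            subset_start_year=sub.start_year,
            subset_duration_years=sub.duration_years,
            start_decade=sub.start_decade, n_decades=sub.n_decades,
            effect_size=float(best.glm.params[1]),
            # exponent capped: separated subsets give divergent coefficients
            odds_ratio=float(np.exp(min(best.glm.params[1], 100.0))),
            midpoint=best.window.midpoint,
            duration=best.window.duration,
        ))
    if len(results) < 4:
        raise ValueError("too few usable subsets for meta-regression")
    start = np.array([r.start_decade for r in results], dtype=float)
    dur = np.array([r.n_decades for r in results], dtype=float)
    meta = {
        "effect_size": _meta_ols("effect_size",
                                 np.array([r.effect_size for r in results]),
                                 start, dur),
        "midpoint": _meta_ols("midpoint",
                              np.array([r.midpoint for r in results]),
                              start, dur),
        "duration": _meta_ols("duration",
                              np.array([float(r.duration) for r in results]),
                              start, dur),
    }
    return results, meta


def kfold_blocks(years: Sequence[int], block: int = DEFAULT_BLOCK
                 ) -> list[tuple[list[int], list[int]]]:
    """Consecutive blocks of ``block`` years; each fold is (training years,
    held-out block).  Any remainder forms a final, shorter block."""
    ys = sorted(years)
    held = [ys[i:i + block] for i in range(0, len(ys), block)]
    folds = []
    for h in held:
        hs = set(h)
        folds.append(([y for y in ys if y not in hs], list(h)))
    return folds


@dataclass
class CVSummary:
    """Held-out predictions of block K-fold cross-validation."""

    records: pd.DataFrame = field(repr=False)  # year, fold, observed, predicted, prob
    n_folds: int = 0
    skipped_folds: list[int] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        r = self.records
        return float((r["observed"] == r["predicted"]).mean())

    @property
    def raw_discrepancy(self) -> int:
        r = self.records
        return int((r["predicted"] - r["observed"]).sum())

    def summary(self) -> str:
        return (f"K-fold CV: {self.n_folds} folds, {len(self.records)} "
                f"predictions, accuracy={self.accuracy:.3f}, "
                f"raw discrepancy={self.raw_discrepancy:+d}")


def cross_validate(temps: DailySeries, status: Sequence[YearVoltinism],
                   variable: str, block: int = DEFAULT_BLOCK) -> CVSummary:
    """Leave-block-out re-scan and prediction of second-flight presence.

    Per fold, a full sliding-window scan is run on the training years only;
    the best model predicts the held-out years, with fitted probability
    >= 0.5 classed as presence (the exact tie goes to presence).
    """
    classified = {v.year: v for v in status if v.status in ("one", "two")}
    folds = kfold_blocks(sorted(classified), block=block)
    rows = []
    skipped = []
    for i, (train_years, held_years) in enumerate(folds):
        train_status = [classified[y] for y in train_years]
        try:
            grid = scan_variable(temps, train_status, variable, compute_ci=False)
        except ScanError:
            skipped.append(i)
            continue
        best = grid.best
        for y in held_years:
            x = window_mean(temps, variable, best.window, y)
            prob = float(best.glm.predict([x])[0])
            pred = 1 if prob >= 0.5 else 0
            obs = 1 if classified[y].status == "two" else 0
            rows.append({"year": y, "fold": i, "observed": obs,
                         "predicted": pred, "probability": prob})
    return CVSummary(records=pd.DataFrame(rows), n_folds=len(folds) - len(skipped),
                     skipped_folds=skipped)
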