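"""Density dependence of first-flight-period abundance.

The yearly response is the number of individuals hard-assigned to the first
flight period.  Candidate drivers are the size of the previous flight period
(the second period of a bivoltine previous year, otherwise that year's only
period), the previous year's voltinism as a two-level factor, their
interaction, and the overwinter temperature (mean daily mean from 1 October
of the previous year through 30 June).  A top-down NB2 model selection with
likelihood-ratio tests prunes the model; terms with 0.05 <= p < 0.1 are
flagged marginal.

Exclusion rules: equipment-failure years and the year immediately after
each are absent (the lag covariate would be undefined); zero-catch years
without recorded failure enter as zero counts; the first study year has no
lag and is absent.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import CatchSeries, DailySeries, week_of_year
from .flight_periods import MixtureResults, YearVoltinism
from .stats_core import FitError, LrtResult, NbFit, fit_negbin_glm, likelihood_ratio_test

__all__ = ["AbundanceTable", "SelectionTrace", "oct_june_mean",
           "build_abundance_table", "select_abundance_model"]


def oct_june_mean(temps: DailySeries, year: int) -> float:
    """Mean daily mean temperature, 1 Oct of ``year - 1`` through 30 Jun."""
    vm = temps.value_map("mean")
    d = dt.date(year - 1, 10, 1)
    end = dt.date(year, 6, 30)
    total, n = 0.0, 0
    while d <= end:
        if d not in vm or np.isnan(vm[d]):
            raise ValueError(f"temperature missing on {d} in the Oct-Jun span")
        total += vm[d]
        n += 1
        d += dt.timedelta(days=1)
    return total / n


@dataclass
class AbundanceTable:
    """Year-level rows: response count, lagged covariates, overwinter mean."""

    frame: pd.DataFrame = field(repr=False)
    # columns: year, first_period_count, prev_period_count, prev_voltinism,
    #          oct_jun_mean

    def __len__(self) -> int:
        return len(self.frame)


def _generation_counts(catches: CatchSeries, fit: MixtureResults
                       ) -> dict[int, tuple[int, int]]:
    """year -> (first-period individuals, second-period individuals)."""
    boundary_p2 = fit.posterior_second
    out: dict[int, list[int]] = {}
    for date, count in zip(catches.frame["date"], catches.frame["count"]):
        if count <= 0:
            continue
        gen = 2 if float(boundary_p2([week_of_year(date)])[0]) > 0.5 else 1
        c = out.setdefault(date.year, [0, 0])
        c[gen - 1] += int(count)
    return {y: (c[0], c[1]) for y, c in out.items()}


def build_abundance_table(catches: CatchSeries, status: Sequence[YearVoltinism],
                          fit: MixtureResults, temps: DailySeries) -> AbundanceTable:
    """Assemble the abundance rows per the exclusion and lag rules."""
    by_year = {v.year: v for v in status}
    years = sorted(by_year)
    failures = {v.year for v in status
                if v.exclusion_reason == "equipment-failure"}
    counts = _generation_counts(catches, fit)
    rows = []
    first_year = years[0]
    for year in years:
        if year == first_year or year in failures or (year - 1) in failures:
            continue
        prev = by_year.get(year - 1)
        if prev is None:
            continue
        c1, c2 = counts.get(year, (0, 0))
        p1, p2 = counts.get(year - 1, (0, 0))
        if prev.status == "two":
            prev_count, prev_volt = p2, "two"
        else:
            # univoltine or zero-catch previous year: its only (possibly
            # empty) flight period is the lag
            prev_count, prev_volt = p1 + p2, "one"
        rows.append({
            "year": year,
            "first_period_count": c1,
            "prev_period_count": prev_count,
            "prev_voltinism": prev_volt,
            "oct_jun_mean": oct_june_mean(temps, year),
        })
    return AbundanceTable(frame=pd.DataFrame(rows))


@dataclass
class TraceEntry:
    """One elimination step: the term tested by dropping it."""

    term: str
    formula: str          # model the term was dropped FROM
    loglik_with: float
    loglik_without: float
    lrt: LrtResult
    action: str           # 'dropped' | 'retained' | 'marginal'


@dataclass
class SelectionTrace:
    """Ordered record of the top-down NB2 selection."""

    entries: list[TraceEntry]
    final: NbFit
    final_terms: tuple[str, ...]
    marginal_terms: tuple[str, ...]

    def summary(self) -> str:
        lines = ["Top-down NB2 selection:"]
        for e in self.entries:
            lines.append(f"  drop {e.term:<28s} 2dLL={e.lrt.statistic:6.2f} "
                         f"df={e.lrt.df} p={e.lrt.pvalue:.4f} -> {e.action}")
        lines.append(f"  final terms: {list(self.final_terms)}")
        if self.marginal_terms:
            lines.append(f"  marginal (0.05<=p<0.1): {list(self.marginal_terms)}")
        lines.append(self.final.summary())
        return "\n".join(lines)


_TERMS = ("prev_period_count", "prev_voltinism_two", "interaction", "oct_jun_mean")


def _design(table: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame | None:
    cols = {}
    volt = (table["prev_voltinism"] == "two").astype(float)
    for t in terms:
        if t == "prev_period_count":
            cols[t] = table["prev_period_count"].astype(float)
        elif t == "prev_voltinism_two":
            cols[t] = volt
        elif t == "interaction":
            cols[t] = table["prev_period_count"].astype(float) * volt
        elif t == "oct_jun_mean":
            cols[t] = table["oct_jun_mean"].astype(float)
        else:
            raise ValueError(f"unknown term {t}")
    return pd.DataFrame(cols) if cols else None


def select_abundance_model(table: AbundanceTable, alpha: float = 0.05,
                           marginal_band: float = 0.1) -> SelectionTrace:
    """Backward elimination from the full NB2 model by likelihood-ratio test.

    The interaction is considered first; a main effect is only droppable
    while the interaction is out.  At each step the least significant
    droppable term with p >= alpha is removed; remaining terms with
    p < alpha are retained, and those in [alpha, marginal_band) are kept out
    of the final model but flagged marginal.
    """
    frame = table.frame
    if len(frame) < 10:
        raise FitError(f"need at least 10 abundance rows, have {len(frame)}")
    y = frame["first_period_count"].to_numpy()

    def fit(terms: Sequence[str]) -> NbFit:
        return fit_negbin_glm(y, _design(frame, terms))

    current = list(_TERMS)
    entries: list[TraceEntry] = []
    marginal: list[str] = []
    full_fit = fit(current)
    while True:
        droppable = [t for t in current
                     if t != "interaction"
                     and not (t in ("prev_period_count", "prev_voltinism_two")
                              and "interaction" in current)]
        if "interaction" in current:
            droppable = ["interaction"] + droppable
        tests = []
        for t in droppable:
            reduced = fit([u for u in current if u != t])
            lrt = likelihood_ratio_test(full_fit, reduced)
            tests.append((t, reduced, lrt))
        if not tests:
            break
        t, reduced, lrt = max(tests, key=lambda r: r[2].pvalue)
        if lrt.pvalue < alpha:
            for tt, _red, tlrt in tests:
                entries.append(TraceEntry(
                    term=tt, formula="+".join(current),
                    loglik_with=full_fit.loglik, loglik_without=_red.loglik,
                    lrt=tlrt, action="retained"))
            break
        action = "marginal" if lrt.pvalue < marginal_band else "dropped"
        if action == "marginal":
            marginal.append(t)
        entries.append(TraceEntry(term=t, formula="+".join(current),
                                  loglik_with=full_fit.loglik,
                                  loglik_without=reduced.loglik,
                                  lrt=lrt, action=action))
        current.remove(t)
        full_fit = reduced
        if not current:
            break
    return SelectionTrace(entries=entries, final=full_fit,
                          final_terms=tuple(current),
                          marginal_terms=tuple(marginal))
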