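"""End-to-end study object: classify, scan, validate, model abundance.

:class:`VoltinismStudy` is the model built from a catch series and a daily
temperature series under a :class:`PipelineConfig`; its :meth:`fit` runs the
stages in order (flight-period mixture -> year classification -> presence
trend -> three-variable window scan -> threshold/warming trend -> subset
sensitivity and block cross-validation -> abundance model selection) and
returns a :class:`StudyResults` carrying every stage's results, with a
``summary()`` table and serialization of all artifacts to a directory.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import trends as tr
from . import validation as va
from . import window_scan as ws
from .data_io import CatchSeries, DailySeries
from .flight_periods import (
    MixtureResults,
    YearVoltinism,
    classify_years,
    fit_mixture,
    weekly_observations,
)
from .stats_core import GlmFit, LmFit, OddsRatio, mcfadden_r2

logger = logging.getLogger("voltiscan")

__all__ = ["PipelineConfig", "VoltinismStudy", "StudyResults"]


@dataclass
class PipelineConfig:
    """All tunable settings; the defaults reproduce the study design."""

    catches_path: str | None = None
    temps_path: str | None = None
    failure_years: tuple[int, ...] = ()          # equipment-failure exclusions
    year_range: tuple[int, int] | None = None    # study span; catch span if None
    posterior_threshold: float = 0.999
    per_individual: bool = True                  # one mixture obs per individual
    mixture_restarts: int = 10
    require_end_within_season: bool = False
    subset_scheme: str = "exhaustive"
    cv_block: int = 5
    selection_alpha: float = 0.05
    run_validation: bool = True
    run_abundance: bool = True
    output_dir: str = "voltiscan_out"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.posterior_threshold < 1.0):
            raise ValueError(
                f"posterior_threshold must lie in (0, 1), got {self.posterior_threshold}")
        if self.subset_scheme not in ("exhaustive", "nested"):
            raise ValueError(f"unknown subset scheme {self.subset_scheme!r}")
        if self.cv_block < 1:
            raise ValueError("cv_block must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("failure_years", "year_range"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["failure_years"] = list(self.failure_years)
        d["year_range"] = list(self.year_range) if self.year_range else None
        return d


@dataclass
class StudyResults:
    """Everything the pipeline computes, stage by stage."""

    config: PipelineConfig
    mixture: MixtureResults
    classification: list[YearVoltinism]
    presence_trend: GlmFit
    presence_or: OddsRatio
    grids: dict[str, ws.ScanGrid]
    best: ws.WindowFit
    threshold: tr.ThresholdResult
    temperature_trend: LmFit
    trend_years: list[int]
    subset_results: list[va.SubsetResult] | None = None
    subset_meta: dict[str, va.MetaRegression] | None = None
    cv: va.CVSummary | None = None
    abundance_table: ab.AbundanceTable | None = None
    selection: ab.SelectionTrace | None = None
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def n_two_flight_years(self) -> int:
        return sum(1 for v in self.classification if v.status == "two")

    def summary(self) -> str:
        b = self.best
        first, last = b.window.dates(self.trend_years[-1])
        lines = [
            "=" * 64,
            "Voltinism shift analysis",
            "=" * 64,
            self.mixture.summary(),
            "",
            f"Years with two flight periods: {self.n_two_flight_years} of "
            f"{sum(1 for v in self.classification if v.status != 'excluded')} classified",
            f"Presence ~ year: OR/yr = {self.presence_or.point:.3f} "
            f"[{self.presence_or.lower:.3f}, {self.presence_or.upper:.3f}]",
            "",
            "Best windows by variable:",
        ]
        for var in ws.VARIABLE_ORDER:
            if var in self.grids:
                lines.append("  " + self.grids[var].best.summary())
        lines += [
            f"Overall winner: {b.variable} temperature, {b.window.duration}-day "
            f"window {first.strftime('%d %b')}-{last.strftime('%d %b')} "
            f"(season days {b.window.start}..{b.window.start + b.window.duration - 1})",
            f"Threshold temperature (p=0.5): {self.threshold.threshold_temp:.2f} degC",
            f"Window {b.variable} temperature trend: "
            f"{self.temperature_trend.slope:.4f} degC/yr "
            f"(t_(1,{self.temperature_trend.df_resid})={self.temperature_trend.t:.2f}, "
            f"p={self.temperature_trend.pvalue:.2g})",
            f"Trend crosses threshold in: {self.threshold.crossing_year}",
        ]
        if self.cv is not None:
            lines += ["", self.cv.summary()]
        if self.subset_meta is not None:
            md = self.subset_meta["duration"]
            lines.append(
                f"Subset sensitivity: window duration changes "
                f"{md.coef_start:+.2f} d per decade of later start "
                f"(t_(1,{md.df_resid})={md.t_start:.2f}, p={md.p_start:.3f})")
        if self.selection is not None:
            lines += ["", self.selection.summary()]
        return "\n".join(lines)

    def headline(self) -> dict:
        """Flat dict of the study's headline numbers."""
        b = self.best
        out = {
            "mixture_mu1_weeks": self.mixture.mu1,
            "mixture_mu2_weeks": self.mixture.mu2,
            "mixture_sigma_weeks": self.mixture.sigma,
            "n_observations": self.mixture.n_obs,
            "n_two_flight_years": self.n_two_flight_years,
            "presence_or_per_year": self.presence_or.point,
            "presence_or_lower": self.presence_or.lower,
            "presence_or_upper": self.presence_or.upper,
            "best_variable": b.variable,
            "best_window_start": b.window.start,
            "best_window_duration_days": b.window.duration,
            "best_window_midpoint": b.window.midpoint,
            "best_pseudo_r2": b.pseudo_r2,
            "window_or_per_degC": (b.odds_ratio.point if b.odds_ratio
                                   else float(np.exp(b.glm.params[1]))),
            "threshold_temp_degC": self.threshold.threshold_temp,
            "trend_degC_per_year": self.temperature_trend.slope,
            "trend_t": self.temperature_trend.t,
            "crossing_year": self.threshold.crossing_year,
        }
        if self.cv is not None:
            out["cv_accuracy"] = self.cv.accuracy
            out["cv_raw_discrepancy"] = self.cv.raw_discrepancy
        if self.selection is not None:
            out["abundance_terms"] = list(self.selection.final_terms)
            coef = self.selection.final.coefficients.get("prev_period_count")
            if coef is not None:
                out["abundance_lag_factor"] = float(np.exp(coef))
        return out

    def write(self, outdir: str | Path) -> None:
        """Serialize every stage's results as CSV/JSON under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)

        def dump(obj, name):
            (out / name).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                               default=_json_default))

        dump({"mu1": self.mixture.mu1, "mu2": self.mixture.mu2,
              "sigma": self.mixture.sigma, "weights": list(self.mixture.weights),
              "loglik": self.mixture.loglik, "n_obs": self.mixture.n_obs,
              "lr_vs_single_normal": self.mixture.lr_vs_single_normal},
             "mixture.json")
        pd.DataFrame([{"year": v.year, "status": v.status,
                       "max_posterior2": v.max_posterior2,
                       "exclusion_reason": v.exclusion_reason}
                      for v in self.classification]).to_csv(
            out / "classification.csv", index=False)
        grid_rows = []
        for g in self.grids.values():
            grid_rows.extend(g.as_records())
        pd.DataFrame(grid_rows).to_csv(out / "scan_grid.csv", index=False)
        b = self.best
        dump({"variable": b.variable, "start": b.window.start,
              "duration": b.window.duration, "midpoint": b.window.midpoint,
              "pseudo_r2": b.pseudo_r2,
              "coef": list(b.glm.params),
              "odds_ratio": (None if b.odds_ratio is None else
                             [b.odds_ratio.point, b.odds_ratio.lower,
                              b.odds_ratio.upper])}, "best_window.json")
        dump({"or_per_year": [self.presence_or.point, self.presence_or.lower,
                              self.presence_or.upper],
              "threshold_temp": self.threshold.threshold_temp,
              "trend_slope": self.temperature_trend.slope,
              "trend_t": self.temperature_trend.t,
              "trend_p": self.temperature_trend.pvalue,
              "crossing_year": self.threshold.crossing_year}, "trends.json")
        if self.subset_results is not None:
            pd.DataFrame([dataclasses.asdict(r) for r in self.subset_results]
                         ).to_csv(out / "subset_windows.csv", index=False)
            dump({k: dataclasses.asdict(v) for k, v in self.subset_meta.items()},
                 "subset_meta.json")
        if self.cv is not None:
            self.cv.records.to_csv(out / "cv_predictions.csv", index=False)
        if self.abundance_table is not None:
            self.abundance_table.frame.to_csv(out / "abundance_table.csv",
                                              index=False)
        if self.selection is not None:
            dump({"entries": [{"term": e.term, "formula": e.formula,
                               "statistic": e.lrt.statistic, "df": e.lrt.df,
                               "pvalue": e.lrt.pvalue, "action": e.action}
                              for e in self.selection.entries],
                  "final_terms": list(self.selection.final_terms),
                  "marginal_terms": list(self.selection.marginal_terms),
                  "coefficients": self.selection.final.coefficients,
                  "k": self.selection.final.k,
                  "loglik": self.selection.final.loglik}, "selection.json")
        dump(self.headline(), "summary.json")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


class VoltinismStudy:
    """The full analysis as a fit-once model object."""

    def __init__(self, catches: CatchSeries, temps: DailySeries,
                 config: PipelineConfig | None = None):
        self.catches = catches
        self.temps = temps
        self.config = config or PipelineConfig()

    def fit(self) -> StudyResults:
        cfg = self.config
        timings: dict[str, float] = {}

        def stage(name):
            logger.info("stage %s", name)
            timings[name] = time.perf_counter()

        def done(name):
            timings[name] = time.perf_counter() - timings[name]
            logger.info("stage %s done in %.2fs", name, timings[name])

        stage("mixture")
        obs = weekly_observations(self.catches, per_individual=cfg.per_individual)
        mixture = fit_mixture(obs["week"].to_numpy(),
                              restarts=cfg.mixture_restarts, seed=cfg.seed)
        done("mixture")

        stage("classification")
        years = (range(cfg.year_range[0], cfg.year_range[1] + 1)
                 if cfg.year_range else None)
        classification = classify_years(
            self.catches, mixture, threshold=cfg.posterior_threshold,
            known_failures=cfg.failure_years, years=years,
            per_individual=cfg.per_individual)
        done("classification")

        stage("presence_trend")
        presence_fit, presence_or = tr.fit_presence_trend(classification)
        done("presence_trend")

        stage("window_scan")
        windows = ws.enumerate_windows(cfg.require_end_within_season)
        grids = {var: ws.scan_variable(self.temps, classification, var,
                                       windows=windows)
                 for var in ws.VARIABLE_ORDER}
        best = ws.best_overall(grids)
        done("window_scan")

        stage("trends")
        threshold_temp = tr.threshold_temperature(best.glm)
        trend_years = self._trend_years(best.window, best.variable,
                                        classification)
        temp_trend = tr.window_temperature_trend(
            self.temps, best.window, trend_years, variable=best.variable)
        threshold = tr.crossing_year(temp_trend, threshold_temp,
                                     first_year=trend_years[0])
        done("trends")

        subset_results = subset_meta = cv = None
        if cfg.run_validation:
            stage("validation")
            subset_results, subset_meta = va.subset_sensitivity(
                self.temps, classification, best.variable,
                scheme=cfg.subset_scheme)
            cv = va.cross_validate(self.temps, classification, best.variable,
                                   block=cfg.cv_block)
            done("validation")

        table = selection = None
        if cfg.run_abundance:
            stage("abundance")
            table = ab.build_abundance_table(self.catches, classification,
                                             mixture, self.temps)
            selection = ab.select_abundance_model(table,
                                                  alpha=cfg.selection_alpha)
            done("abundance")

        return StudyResults(
            config=cfg, mixture=mixture, classification=classification,
            presence_trend=presence_fit, presence_or=presence_or,
            grids=grids, best=best, threshold=threshold,
            temperature_trend=temp_trend, trend_years=trend_years,
            subset_results=subset_results, subset_meta=subset_meta, cv=cv,
            abundance_table=table, selection=selection, timings=timings)

    def _trend_years(self, window: ws.WindowSpec, variable: str,
                     classification: Sequence[YearVoltinism]) -> list[int]:
        """Every study year whose window has full temperature coverage (the
        warming trend uses the whole record, without moth-data exclusions)."""
        years = [v.year for v in classification]
        out = []
        for y in years:
            try:
                ws.window_mean(self.temps, variable, window, y)
            except ws.ScanError:
                continue
            out.append(y)
        if len(out) < 3:
            raise ws.ScanError("too few years with window temperature coverage")
        return out
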