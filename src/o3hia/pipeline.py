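"""End-to-end orchestration of the mortality-projection pipeline.

The causal chain runs: hourly gridded model ozone -> city-level daily MDA8
-> per-member quantile bias correction against observations -> ensemble
member averaging -> demographic scaling of baseline mortality -> daily
attributable deaths above the background threshold -> annual burdens per
model -> pooling across models -> Monte Carlo confidence intervals ->
present/future comparison -> driver decomposition.

Baseline mortality enters as a day-of-year climatology: the observed daily
death counts of the training years are averaged per calendar day and
paired with each projection day by its day of year, then scaled by the
country's demographic change factors for the scenario and period.  This
lets a three-year mortality record supply the baseline for five-year
concentration windows in both periods symmetrically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import synthetic_data
from .bias_correction import apply_bias_maps, fit_bias_maps, summarize_bias
from .decomposition import decompose_drivers
from .demographics import lookup_factors
from .errors import ComputationError, ConfigError
from .exposure import average_members, extract_city_series
from .hia import (ExposureResponse, annual_burden_for_betas, compare_periods,
                  pool_models)
from .seeding import substream
from .uncertainty import change_ci, empirical_ci, sample_coefficients

logger = logging.getLogger(__name__)

__all__ = ["RunSettings", "World", "PipelineResult", "build_world", "run_world"]


@dataclass
class RunSettings:
    """Analysis-stage knobs, independent of how the inputs were produced."""

    ci_level: float = 95.0
    n_draws: int = 1000
    seed: int = 0
    grid_size: int = 101
    min_month_n: int = 30
    guideline: float | None = None   # optional WHO-style day filter (ug/m3)

    def validate(self) -> None:
        if not 0 < self.ci_level < 100:
            raise ConfigError("ci_level must lie in (0, 100)")
        if self.n_draws < 2:
            raise ConfigError("n_draws must be at least 2")
        if self.grid_size < 2:
            raise ConfigError("grid_size must be at least 2")


@dataclass
class World:
    """All pipeline inputs, with gridded fields supplied lazily."""

    registry: pd.DataFrame
    observed: pd.DataFrame                  # city_id, date, o3_mda8_ugm3, deaths
    factors: pd.DataFrame                   # demographic change factors
    erf: pd.DataFrame                       # exposure-response table
    models: Sequence[str]
    members: Mapping[str, Sequence[str]]    # model_id -> member ids
    scenarios: Sequence[str]
    years_hist: Sequence[int]
    field_provider: Callable[[str, str, str, str], object]  # model, member, scenario, period


@dataclass
class PipelineResult:
    burdens: pd.DataFrame        # per city x model (and pooled) x scenario x period
    totals: pd.DataFrame         # all-city totals with empirical CIs
    changes: pd.DataFrame        # present -> future changes with CIs
    decomposition: pd.DataFrame  # driver components per country and overall
    bias_summary: pd.DataFrame   # raw-model mean bias per model (training window)
    log: dict = field(default_factory=dict)


def build_world(cfg: synthetic_data.SyntheticWorldConfig) -> World:
    """Assemble an in-memory synthetic world from one generator config."""
    cfg.validate()
    registry = synthetic_data.generate_city_registry(cfg)
    return World(
        registry=registry,
        observed=synthetic_data.generate_observed_series(registry, cfg),
        factors=synthetic_data.generate_demographics(registry, cfg),
        erf=synthetic_data.generate_exposure_response(registry, cfg),
        models=cfg.model_ids,
        members={m: list(cfg.member_ids) for m in cfg.model_ids},
        scenarios=list(cfg.scenarios),
        years_hist=list(cfg.years_hist),
        field_provider=lambda model, member, scenario, period: synthetic_data.field_for(
            registry, cfg, model, member, scenario, period),
    )


def _death_profile(observed: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-city mean daily deaths by day of year (index 0 = Jan 1)."""
    profiles: dict[str, np.ndarray] = {}
    doy = pd.DatetimeIndex(observed["date"]).dayofyear.to_numpy()
    for city_id, grp_idx in observed.groupby("city_id").indices.items():
        deaths = observed["deaths"].to_numpy(dtype=float)[grp_idx]
        d = doy[grp_idx]
        prof = np.full(366, np.nan)
        sums = np.bincount(d - 1, weights=deaths, minlength=366)
        counts = np.bincount(d - 1, minlength=366)
        has = counts > 0
        prof[has] = sums[has] / counts[has]
        if np.isnan(prof[365]):     # no Feb 29 in the training years
            prof[365] = prof[364]
        if np.isnan(prof).any():
            raise ComputationError(
                f"city {city_id!r}: observed deaths do not cover every day of year")
        profiles[city_id] = prof
    return profiles


def _corrected_concentrations(world: World, settings: RunSettings):
    """Extract, bias-correct per member, and average members per model.

    Returns (conc, bias_rows): ``conc[(model, scenario, period)]`` is a tidy
    city/date/o3 frame; bias_rows summarise the raw-model training bias.
    """
    obs_o3 = world.observed[["city_id", "date", "o3_mda8_ugm3"]]
    hist_years = set(world.years_hist)
    conc: dict[tuple[str, str, str], pd.DataFrame] = {}
    bias_rows = []
    for model in world.models:
        present_members, future_members = [], {s: [] for s in world.scenarios}
        for member in world.members[model]:
            fld = world.field_provider(model, member, "historical", "present")
            present = extract_city_series(fld, world.registry)
            train = present[pd.DatetimeIndex(present["date"]).year.isin(hist_years)]
            maps = fit_bias_maps(obs_o3, train, grid_size=settings.grid_size,
                                 min_month_n=settings.min_month_n, model_id=model)
            raw = summarize_bias(obs_o3, train)
            pooled = raw[raw["city_id"] == "(pooled)"].iloc[0]
            bias_rows.append((model, member, pooled["mean"], pooled["min"], pooled["max"]))
            present_members.append(apply_bias_maps(maps, present))
            for scen in world.scenarios:
                fld_f = world.field_provider(model, member, scen, "future")
                future = extract_city_series(fld_f, world.registry)
                future_members[scen].append(apply_bias_maps(maps, future))
        conc[(model, "historical", "present")] = average_members(present_members)
        for scen in world.scenarios:
            conc[(model, scen, "future")] = average_members(future_members[scen])
    bias_summary = pd.DataFrame(
        bias_rows, columns=["model_id", "member_id", "mean_bias", "min_bias", "max_bias"])
    return conc, bias_summary


def run_world(world: World, settings: RunSettings | None = None) -> PipelineResult:
    """Run the full projection pipeline on in-memory inputs."""
    settings = settings or RunSettings()
    settings.validate()

    profiles = _death_profile(world.observed)
    country_of = dict(zip(world.registry["city_id"], world.registry["country_id"]))
    erf_of: dict[str, ExposureResponse] = {}
    draws_of: dict[str, np.ndarray] = {}
    for r in world.erf.itertuples(index=False):
        erf = ExposureResponse(country_id=r.country_id, beta=float(r.beta_per_ugm3),
                               se_beta=float(r.se_beta), threshold=float(r.threshold_ugm3))
        erf_of[r.country_id] = erf
        seed = substream(settings.seed, "coef", r.country_id).integers(0, 2**31 - 1)
        draws_of[r.country_id] = sample_coefficients(erf, settings.n_draws, int(seed)).draws

    conc, bias_summary = _corrected_concentrations(world, settings)
    cities = list(world.registry["city_id"])

    # point burdens and draw-level burdens per (model, scenario, period, city)
    burden_rows = []
    point: dict[tuple, dict[str, float]] = {}
    draws: dict[tuple, dict[str, np.ndarray]] = {}
    denom: dict[tuple[str, str], float] = {}   # scaled total deaths/year per scenario/period
    for (model, scen, period), table in conc.items():
        pt, dw = {}, {}
        dates_by_city = table.groupby("city_id")
        denom_key = (scen, period)
        denom_total = 0.0
        for city in cities:
            sub = dates_by_city.get_group(city)
            dates = pd.DatetimeIndex(sub["date"])
            c = sub["o3_mda8_ugm3"].to_numpy(dtype=float)
            country = country_of[city]
            dy, dp = lookup_factors(world.factors, country, scen, period)
            m = profiles[city][dates.dayofyear.to_numpy() - 1] * dy * dp
            n_years = dates.year.nunique()
            erf = erf_of[country]
            burdens = annual_burden_for_betas(
                c, m, np.concatenate([[erf.beta], draws_of[country]]),
                threshold=erf.threshold, n_years=n_years, guideline=settings.guideline)
            pt[city] = float(burdens[0])
            dw[city] = burdens[1:]
            total_deaths_year = float(m.sum()) / n_years
            denom_total += total_deaths_year
            burden_rows.append((city, country, scen, period, model,
                                pt[city], pt[city] / total_deaths_year,
                                np.nan, np.nan))
        point[(model, scen, period)] = pt
        draws[(model, scen, period)] = dw
        denom[denom_key] = denom_total

    level = settings.ci_level
    period_keys = [("historical", "present")] + [(s, "future") for s in world.scenarios]

    pooled_rows, totals_rows = [], []
    totals_point: dict[tuple[str, str], float] = {}
    totals_ci: dict[tuple[str, str], tuple[float, float]] = {}
    for scen, period in period_keys:
        model_totals = []
        total_draws = []
        for model in world.models:
            pt = point[(model, scen, period)]
            model_totals.append(sum(pt.values()))
            total_draws.append(np.sum([draws[(model, scen, period)][c] for c in cities], axis=0))
        for city in cities:
            city_point, _ = pool_models([point[(m, scen, period)][city] for m in world.models])
            city_draws = np.concatenate([draws[(m, scen, period)][city] for m in world.models])
            lo, hi = empirical_ci(city_draws, level)
            pooled_rows.append((city, country_of[city], scen, period, "pooled",
                                city_point, np.nan, lo, hi))
        tot_point, (tot_min, tot_max) = pool_models(model_totals)
        tot_lo, tot_hi = empirical_ci(np.concatenate(total_draws), level)
        totals_point[(scen, period)] = tot_point
        totals_ci[(scen, period)] = (tot_lo, tot_hi)
        d = denom[(scen, period)]
        totals_rows.append((scen, period, tot_point, tot_min, tot_max, tot_lo, tot_hi,
                            tot_point / d, tot_lo / d, tot_hi / d))

    burdens = pd.DataFrame(
        burden_rows + pooled_rows,
        columns=["city_id", "country_id", "scenario_id", "period_id", "model_id",
                 "deaths_per_year", "af_total", "eci_low", "eci_high"])
    totals = pd.DataFrame(
        totals_rows,
        columns=["scenario_id", "period_id", "deaths_per_year", "model_min", "model_max",
                 "eci_low", "eci_high", "af_total", "af_eci_low", "af_eci_high"])

    # present -> future changes with the translation CI rule
    present_total = totals_point[("historical", "present")]
    change_rows = []
    for scen in world.scenarios:
        ch = compare_periods(present_total, totals_point[(scen, "future")])
        lo, hi = change_ci(present_total, totals_ci[(scen, "future")])
        pct_lo, pct_hi = (100.0 * lo / present_total, 100.0 * hi / present_total) \
            if present_total else (np.nan, np.nan)
        change_rows.append((scen, ch.delta, ch.pct if ch.pct_defined else np.nan,
                            ch.pct_defined, lo, hi, pct_lo, pct_hi))
    changes = pd.DataFrame(change_rows, columns=[
        "scenario_id", "delta_deaths_per_year", "pct_change", "pct_defined",
        "ci_low", "ci_high", "pct_ci_low", "pct_ci_high"])

    # driver decomposition on pooled city means, aggregated per country + total
    decomp_rows = []
    for scen in world.scenarios:
        by_country_present: dict[str, float] = {}
        by_country_future: dict[str, float] = {}
        for city in cities:
            country = country_of[city]
            p, _ = pool_models([point[(m, "historical", "present")][city] for m in world.models])
            f, _ = pool_models([point[(m, scen, "future")][city] for m in world.models])
            by_country_present[country] = by_country_present.get(country, 0.0) + p
            by_country_future[country] = by_country_future.get(country, 0.0) + f
        total_comp = np.zeros(3)
        for country in sorted(by_country_present):
            pf = lookup_factors(world.factors, country, "historical", "present")
            ff = lookup_factors(world.factors, country, scen, "future")
            dc = decompose_drivers(by_country_present[country], by_country_future[country],
                                   present_factors=pf, future_factors=ff,
                                   unit_id=country, scenario_id=scen)
            total_comp += (dc.climate, dc.population, dc.rate)
            decomp_rows.append((country, scen, dc.climate, dc.population, dc.rate, dc.total,
                                dc.pct_climate, dc.pct_population, dc.pct_rate))
        tot_present = sum(by_country_present.values())
        tot_total = sum(by_country_future.values()) - tot_present
        pct = (lambda x: 100.0 * x / tot_present) if tot_present else (lambda x: np.nan)
        decomp_rows.append(("(all)", scen, *total_comp, tot_total,
                            pct(total_comp[0]), pct(total_comp[1]), pct(total_comp[2])))
    decomposition = pd.DataFrame(decomp_rows, columns=[
        "unit_id", "scenario_id", "climate", "population", "rate", "total",
        "pct_climate", "pct_population", "pct_rate"])

    return PipelineResult(
        burdens=burdens, totals=totals, changes=changes,
        decomposition=decomposition, bias_summary=bias_summary,
        log={"seed": settings.seed, "n_draws": settings.n_draws,
             "ci_level": settings.ci_level, "n_models": len(world.models),
             "n_cities": len(cities)})
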