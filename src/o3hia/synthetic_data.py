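"""Synthetic world generator for the ozone mortality-projection pipeline.

Emulates, at desk scale, every input the analysis needs: a city registry on
a regular lat/lon grid, observed daily MDA8 ozone and Poisson death counts
over a multi-year historical window, hourly gridded model ozone fields
(with injected, configurable biases, scenario trends and ensemble-member
noise) for a present and a future period, country-level demographic change
factors, and country-level exposure-response functions.

Key constructions chosen for testability:

* Cities are snapped to grid-cell centres, so cell lookup is unambiguous.
* Hourly fields are built by scaling a fixed half-sine diurnal shape
  (daytime hump peaking mid-afternoon, zero at night) so that the daily
  MDA8 of the hourly series equals the intended daily value exactly; MDA8
  extraction is therefore exactly invertible.
* The underlying "true" daily series of each city is drawn from a
  substream keyed by city only, so present- and future-period model fields
  share day-for-day anomalies; with no bias, no trend and no member noise
  the world is exactly period-symmetric.
* All randomness derives from one root seed via labelled substreams, so a
  fixed seed regenerates every artifact byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
import xarray as xr

from .errors import ConfigError
from .exposure import PPB_TO_UGM3
from .hia import beta_from_rr10
from .seeding import substream

__all__ = [
    "SyntheticWorldConfig",
    "generate_city_registry",
    "generate_observed_series",
    "generate_model_fields",
    "field_for",
    "generate_demographics",
    "generate_exposure_response",
    "true_daily_series",
    "diurnal_shape",
]

BIAS_PROFILES = ("none", "shift", "scale", "month_dependent", "quantile_dependent")

#: Default scenario set and the mean present-to-future MDA8 change (ug/m3)
#: injected for each: strong mitigation lowers ozone, weak mitigation
#: raises it, with the regional-rivalry pathway worst.
DEFAULT_TRENDS = {"ssp126": -8.0, "ssp245": 1.0, "ssp370": 9.0, "ssp585": 4.0}

#: Default future-period demographic factors (delta_rate, delta_pop):
#: ageing pushes aggregate baseline mortality rates up in every pathway
#: while population change varies in sign.
DEFAULT_DEMOGRAPHICS = {
    "ssp126": (1.30, 1.10),
    "ssp245": (1.40, 1.15),
    "ssp370": (1.50, 0.95),
    "ssp585": (1.35, 1.10),
}


@dataclass
class SyntheticWorldConfig:
    """Configuration of the synthetic study world.

    Defaults mirror the study design the pipeline targets: five
    chemistry-climate models, four socioeconomic pathways, five-year
    present (2010-2014) and future (2050-2054) windows, a three-year
    observational training window, a 70 ug/m3 background threshold and
    country relative risks in [1.0008, 1.0035] per 10 ug/m3.  City and
    country counts are desk-scale stand-ins for the real network.
    """

    n_cities: int = 20
    n_countries: int = 5
    n_models: int = 5
    members_per_model: int = 1
    scenarios: tuple[str, ...] = ("ssp126", "ssp245", "ssp370", "ssp585")
    years_hist: tuple[int, ...] = (2012, 2013, 2014)
    years_present: tuple[int, ...] = (2010, 2011, 2012, 2013, 2014)
    years_future: tuple[int, ...] = (2050, 2051, 2052, 2053, 2054)
    seed: int = 0
    bias_profile: str = "shift"
    trend_per_scenario: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRENDS))

    # grid geometry (degrees); cities sit at cell centres
    grid_res_deg: float = 2.0
    lat_range: tuple[float, float] = (30.0, 58.0)
    lon_range: tuple[float, float] = (-20.0, 40.0)

    # observed MDA8 ozone process (ug/m3): seasonal sinusoid + truncated noise
    o3_mean: float = 70.0
    o3_seasonal_amp: float = 25.0
    o3_noise_sd: float = 12.0
    o3_peak_doy: float = 196.0          # northern-hemisphere mid-summer peak
    background_ugm3: float = 55.0       # non-city grid cells

    # daily death-count process: Poisson with log-linear seasonal baseline
    deaths_mean: float = 30.0
    deaths_seasonal_amp: float = 0.10   # log scale, winter peak
    deaths_peak_doy: float = 15.0
    ozone_death_beta: float = 0.0       # optional injected true effect per ug/m3 above threshold

    # injected model biases (ug/m3 unless noted)
    bias_shift: float = 4.0             # mean model overestimate
    bias_scale: float = 1.1             # multiplicative profile
    bias_quantile_slope: float = 0.2    # extra bias per ug/m3 anomaly
    member_noise_sd: float = 2.0        # daily ensemble-member perturbation

    # exposure-response functions
    rr_range: tuple[float, float] = (1.0008, 1.0035)
    rr_se_frac: float = 0.25            # se(beta) as a fraction of beta
    threshold: float = 70.0

    # demographic change factors; present period is anchored at (1, 1)
    demog_by_scenario: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS))
    demog_jitter: float = 0.10          # lognormal sd of per-country variation

    missing_rate: float = 0.0           # optional observed-data missingness

    def validate(self) -> None:
        if min(self.n_cities, self.n_countries, self.n_models, self.members_per_model) < 1:
            raise ConfigError("all counts must be at least 1")
        if self.n_countries > self.n_cities:
            raise ConfigError("n_countries cannot exceed n_cities")
        if self.bias_profile not in BIAS_PROFILES:
            raise ConfigError(f"unknown bias_profile {self.bias_profile!r}; "
                              f"choose from {BIAS_PROFILES}")
        if not self.years_hist or not self.years_present or not self.years_future:
            raise ConfigError("year windows must be non-empty")
        if not set(self.years_hist) <= set(self.years_present):
            raise ConfigError("years_hist must lie within years_present")
        if set(self.years_present) & set(self.years_future):
            raise ConfigError("present and future year windows must not overlap")
        pres = period_dates(self.years_present)
        fut = period_dates(self.years_future)
        if len(pres) != len(fut) or not np.array_equal(pres.dayofyear, fut.dayofyear):
            raise ConfigError("present and future windows must have matching "
                              "day-of-year structure (same length and leap pattern)")
        for scen in self.scenarios:
            if scen not in self.trend_per_scenario:
                raise ConfigError(f"no trend configured for scenario {scen!r}")
            if scen not in self.demog_by_scenario:
                raise ConfigError(f"no demographic factors configured for scenario {scen!r}")
            dy, dp = self.demog_by_scenario[scen]
            if dy <= 0 or dp <= 0:
                raise ConfigError("demographic change factors must be positive")
        if self.rr_range[0] <= 0 or self.rr_range[1] <= 0:
            raise ConfigError("relative risks must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")

    @property
    def model_ids(self) -> list[str]:
        return [f"model_{i}" for i in range(self.n_models)]

    @property
    def member_ids(self) -> list[str]:
        return [f"r{i + 1}" for i in range(self.members_per_model)]


def period_dates(years: tuple[int, ...]) -> pd.DatetimeIndex:
    """Daily calendar covering the given (sorted) year list, no gaps."""
    ys = sorted(years)
    return pd.date_range(f"{ys[0]}-01-01", f"{ys[-1]}-12-31", freq="D")


# ---------------------------------------------------------------------------
# registry and grid

def _grid_centers(cfg: SyntheticWorldConfig) -> tuple[np.ndarray, np.ndarray]:
    res = cfg.grid_res_deg
    lat0, lat1 = cfg.lat_range
    lon0, lon1 = cfg.lon_range
    nlat = max(int(math.floor((lat1 - lat0) / res)), 1)
    nlon = max(int(math.floor((lon1 - lon0) / res)), 1)
    lat_c = lat0 + res * (np.arange(nlat) + 0.5)
    lon_c = lon0 + res * (np.arange(nlon) + 0.5)
    return lat_c, lon_c


def generate_city_registry(cfg: SyntheticWorldConfig) -> pd.DataFrame:
    """Cities at distinct grid-cell centres, partitioned into countries.

    The first ``n_countries`` cities seed one country each so every country
    is non-empty; the remainder are assigned at random.
    """
    cfg.validate()
    lat_c, lon_c = _grid_centers(cfg)
    n_cells = len(lat_c) * len(lon_c)
    if cfg.n_cities > n_cells:
        raise ConfigError(f"n_cities={cfg.n_cities} exceeds the {n_cells} available grid cells")
    rng = substream(cfg.seed, "registry")
    cells = rng.choice(n_cells, size=cfg.n_cities, replace=False)
    countries = np.empty(cfg.n_cities, dtype=int)
    countries[: cfg.n_countries] = np.arange(cfg.n_countries)
    if cfg.n_cities > cfg.n_countries:
        countries[cfg.n_countries:] = rng.integers(0, cfg.n_countries,
                                                   size=cfg.n_cities - cfg.n_countries)
    return pd.DataFrame({
        "city_id": [f"city_{i:03d}" for i in range(cfg.n_cities)],
        "country_id": [f"country_{c}" for c in countries],
        "lat": lat_c[cells // len(lon_c)],
        "lon": lon_c[cells % len(lon_c)],
    })


# ---------------------------------------------------------------------------
# observed series

def _seasonal_o3(cfg: SyntheticWorldConfig, doy: np.ndarray) -> np.ndarray:
    return cfg.o3_mean + cfg.o3_seasonal_amp * np.cos(
        2.0 * np.pi * (doy - cfg.o3_peak_doy) / 365.25)


def true_daily_series(cfg: SyntheticWorldConfig, city_id: str,
                      dates: pd.DatetimeIndex) -> np.ndarray:
    """The city's underlying daily MDA8 series (ug/m3) for a period window.

    The anomaly stream is keyed by city only, so windows of equal length
    receive identical anomalies day for day; this makes a zero-trend,
    zero-bias world exactly period-symmetric.
    """
    rng = substream(cfg.seed, "truth", city_id)
    noise = rng.normal(0.0, cfg.o3_noise_sd, size=len(dates)) if cfg.o3_noise_sd > 0 \
        else np.zeros(len(dates))
    return np.maximum(_seasonal_o3(cfg, dates.dayofyear.to_numpy()) + noise, 0.0)


def generate_observed_series(registry: pd.DataFrame,
                             cfg: SyntheticWorldConfig) -> pd.DataFrame:
    """Observed daily MDA8 and death counts per city over the training years.

    Returns a tidy frame (city_id, date, o3_mda8_ugm3, deaths).  Deaths are
    Poisson with a log-linear seasonal baseline and, optionally, a known
    injected ozone effect for end-to-end recovery experiments.
    """
    cfg.validate()
    pres = period_dates(cfg.years_present)
    hist_mask = pres.year.isin(cfg.years_hist)
    hist_dates = pres[hist_mask]
    doy = hist_dates.dayofyear.to_numpy()
    frames = []
    for city_id in registry["city_id"]:
        o3 = true_daily_series(cfg, city_id, pres)[hist_mask]
        log_mu = (math.log(cfg.deaths_mean)
                  + cfg.deaths_seasonal_amp * np.cos(
                      2.0 * np.pi * (doy - cfg.deaths_peak_doy) / 365.25))
        if cfg.ozone_death_beta:
            log_mu = log_mu + cfg.ozone_death_beta * np.maximum(o3 - cfg.threshold, 0.0)
        rng = substream(cfg.seed, "deaths", city_id)
        deaths = rng.poisson(np.exp(log_mu))
        df = pd.DataFrame({"city_id": city_id, "date": hist_dates,
                           "o3_mda8_ugm3": o3, "deaths": deaths})
        if cfg.missing_rate > 0:
            drop = substream(cfg.seed, "missing", city_id).random(len(df)) < cfg.missing_rate
            df = df[~drop]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# gridded model fields

def diurnal_shape() -> tuple[np.ndarray, float]:
    """Fixed 24-hour weight vector and its maximum 8-h window mean.

    A half-sine daytime hump (zero before 07:00 and after 21:00, peaking
    mid-afternoon).  Scaling a day's weights by target/m_star makes the
    day's MDA8 equal the target exactly: night hours are zero, so no
    midnight-crossing window can exceed the in-day maximum.
    """
    h = np.arange(24)
    w = np.maximum(np.sin(np.pi * (h - 6) / 16.0), 0.0)
    window_means = np.array([w[s:s + 8].mean() for s in range(17)])
    return w, float(window_means.max())


_DIURNAL_W, _DIURNAL_MSTAR = diurnal_shape()


def _injected_bias(cfg: SyntheticWorldConfig, values: np.ndarray,
                   months: np.ndarray) -> np.ndarray:
    """Additive model bias (ug/m3) per day, by configured profile."""
    profile = cfg.bias_profile
    if profile == "none":
        return np.zeros_like(values)
    if profile == "shift":
        return np.full_like(values, cfg.bias_shift)
    if profile == "scale":
        return (cfg.bias_scale - 1.0) * values
    month_shift = cfg.bias_shift * (1.0 + np.cos(2.0 * np.pi * (months - 1) / 12.0))
    if profile == "month_dependent":
        return month_shift
    if profile == "quantile_dependent":
        mid_doy = (months - 0.5) * 365.25 / 12.0
        anomaly = values - _seasonal_o3(cfg, mid_doy)
        return month_shift + cfg.bias_quantile_slope * anomaly
    raise ConfigError(f"unknown bias_profile {profile!r}")


def field_for(registry: pd.DataFrame, cfg: SyntheticWorldConfig,
              model_id: str, member_id: str, scenario_id: str,
              period_id: str) -> xr.DataArray:
    """One hourly gridded ozone field (ppb) for a model/member/scenario/period.

    City cells carry the city's true daily series plus the injected bias
    (and, for the future period, the scenario trend and the same bias
    profile evaluated at present-day quantiles, emulating biases that
    persist in time), up-sampled to hourly with the fixed diurnal shape.
    Ensemble-member noise is keyed by (model, member, city) but not by
    period, so a zero-trend world stays period-symmetric.
    """
    cfg.validate()
    if period_id == "present":
        dates = period_dates(cfg.years_present)
        trend = 0.0
    elif period_id == "future":
        dates = period_dates(cfg.years_future)
        if scenario_id not in cfg.trend_per_scenario:
            raise ConfigError(f"no trend configured for scenario {scenario_id!r}")
        trend = float(cfg.trend_per_scenario[scenario_id])
    else:
        raise ConfigError(f"unknown period {period_id!r}")

    lat_c, lon_c = _grid_centers(cfg)
    n_days = len(dates)
    months = dates.month.to_numpy()
    daily = np.full((n_days, len(lat_c), len(lon_c)), cfg.background_ugm3)

    cell_of = {}
    res = cfg.grid_res_deg
    for row in registry.itertuples(index=False):
        i = int(np.clip(np.round((row.lat - lat_c[0]) / res), 0, len(lat_c) - 1))
        j = int(np.clip(np.round((row.lon - lon_c[0]) / res), 0, len(lon_c) - 1))
        cell_of[row.city_id] = (i, j)

    # Anomalies for the future window reuse the present window's day
    # indices (validated to have identical day-of-year structure).
    pres_dates = period_dates(cfg.years_present)
    for city_id, (i, j) in cell_of.items():
        truth = true_daily_series(cfg, city_id, pres_dates)
        bias = _injected_bias(cfg, truth, months)
        noise = (substream(cfg.seed, "member", model_id, member_id, city_id)
                 .normal(0.0, cfg.member_noise_sd, size=n_days)
                 if cfg.member_noise_sd > 0 else 0.0)
        daily[:, i, j] = np.maximum(truth + trend + bias + noise, 0.0)

    hourly = (daily[:, None, :, :] * (_DIURNAL_W / _DIURNAL_MSTAR)[None, :, None, None])
    hourly = hourly.reshape(n_days * 24, len(lat_c), len(lon_c)) / PPB_TO_UGM3
    time = pd.date_range(dates[0], periods=n_days * 24, freq="h")
    da = xr.DataArray(hourly, dims=("time", "lat", "lon"),
                      coords={"time": time, "lat": lat_c, "lon": lon_c}, name="o3")
    da.attrs.update(units="ppb", model_id=model_id, member_id=member_id,
                    scenario_id=scenario_id, period_id=period_id)
    return da


def generate_model_fields(registry: pd.DataFrame, cfg: SyntheticWorldConfig
                          ) -> Iterator[xr.DataArray]:
    """Yield every model/member field: the present-period historical run and
    one future run per scenario."""
    cfg.validate()
    for model_id in cfg.model_ids:
        for member_id in cfg.member_ids:
            yield field_for(registry, cfg, model_id, member_id, "historical", "present")
            for scen in cfg.scenarios:
                yield field_for(registry, cfg, model_id, member_id, scen, "future")


# ---------------------------------------------------------------------------
# demographics and exposure-response

def generate_demographics(registry: pd.DataFrame,
                          cfg: SyntheticWorldConfig) -> pd.DataFrame:
    """Country-level demographic change factors per scenario and period.

    The present period is anchored at (1, 1) — the training years sit
    inside the present window, so historical-to-present change is nil.
    Future factors start from the configured per-scenario values with a
    small lognormal per-country jitter.
    """
    cfg.validate()
    rows = []
    for country_id in sorted(registry["country_id"].unique()):
        rows.append((country_id, "historical", "present", 1.0, 1.0))
        for scen in cfg.scenarios:
            dy, dp = cfg.demog_by_scenario[scen]
            if cfg.demog_jitter > 0:
                rng = substream(cfg.seed, "demog", country_id, scen)
                dy *= float(np.exp(rng.normal(0.0, cfg.demog_jitter)))
                dp *= float(np.exp(rng.normal(0.0, cfg.demog_jitter)))
            if dy <= 0 or dp <= 0:
                raise ConfigError("demographic change factors must be positive")
            rows.append((country_id, scen, "future", dy, dp))
    return pd.DataFrame(rows, columns=["country_id", "scenario_id", "period_id",
                                       "delta_rate", "delta_pop"])


def generate_exposure_response(registry: pd.DataFrame,
                               cfg: SyntheticWorldConfig) -> pd.DataFrame:
    """Country-level exposure-response table.

    Relative risks per 10 ug/m3 are drawn uniformly within the configured
    range; coefficients are stored as log(RR)/10 per ug/m3 with a standard
    error proportional to the coefficient.
    """
    cfg.validate()
    lo, hi = cfg.rr_range
    rows = []
    for country_id in sorted(registry["country_id"].unique()):
        rng = substream(cfg.seed, "erf", country_id)
        rr = float(rng.uniform(lo, hi))
        beta = beta_from_rr10(rr)
        rows.append((country_id, rr, beta, cfg.rr_se_frac * abs(beta), cfg.threshold))
    return pd.DataFrame(rows, columns=["country_id", "rr_per_10ugm3", "beta_per_ugm3",
                                       "se_beta", "threshold_ugm3"])
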