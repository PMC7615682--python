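import math

import numpy as np
import pandas as pd
import pytest

from o3hia.errors import ConfigError
from o3hia.exposure import extract_city_series
from o3hia.synthetic_data import (SyntheticWorldConfig, diurnal_shape, field_for,
                                  generate_city_registry, generate_demographics,
                                  generate_exposure_response,
                                  generate_observed_series, period_dates,
                                  true_daily_series)


def small_cfg(**kw):
    base = dict(n_cities=4, n_countries=2, n_models=1, members_per_model=1,
                scenarios=("ssp370",),
                years_hist=(2013, 2014), years_present=(2013, 2014),
                years_future=(2053, 2054),
                lat_range=(40.0, 48.0), lon_range=(0.0, 10.0), seed=11)
    base.update(kw)
    return SyntheticWorldConfig(**base)


class TestRegistry:
    def test_minimal_world(self):
        reg = generate_city_registry(small_cfg(n_cities=1, n_countries=1))
        assert len(reg) == 1 and reg["country_id"].iloc[0] == "country_0"

    def test_deterministic_regeneration(self):
        cfg = small_cfg()
        pd.testing.assert_frame_equal(generate_city_registry(cfg),
                                      generate_city_registry(cfg))

    def test_every_country_inhabited(self):
        reg = generate_city_registry(small_cfg(n_cities=10, n_countries=3,
                                               lat_range=(30.0, 58.0)))
        assert reg["country_id"].nunique() == 3
        assert reg["city_id"].is_unique
        # distinct grid-resolvable coordinates
        assert not reg.duplicated(["lat", "lon"]).any()

    def test_more_countries_than_cities_rejected(self):
        with pytest.raises(ConfigError):
            generate_city_registry(small_cfg(n_cities=2, n_countries=3))


class TestObservedSeries:
    def test_zero_noise_equals_sinusoid(self):
        cfg = small_cfg(o3_noise_sd=0.0)
        reg = generate_city_registry(cfg)
        obs = generate_observed_series(reg, cfg)
        sub = obs[obs.city_id == reg.city_id.iloc[0]]
        doy = pd.DatetimeIndex(sub["date"]).dayofyear.to_numpy()
        expected = cfg.o3_mean + cfg.o3_seasonal_amp * np.cos(
            2 * np.pi * (doy - cfg.o3_peak_doy) / 365.25)
        np.testing.assert_allclose(sub["o3_mda8_ugm3"], expected, atol=1e-12)

    def test_long_run_mean_matches_configured_level(self):
        """Monte Carlo check: the sample mean over ~10,000 days sits within
        3 standard errors of the configured seasonal mean."""
        cfg = small_cfg()
        dates = pd.date_range("1980-01-01", "2007-12-31", freq="D")  # 28 whole years
        vals = true_daily_series(cfg, "mc_city", dates)
        se = math.sqrt(cfg.o3_noise_sd ** 2 + cfg.o3_seasonal_amp ** 2 / 2) / math.sqrt(len(vals))
        assert abs(vals.mean() - cfg.o3_mean) < 3 * se

    def test_deaths_are_nonnegative_integers_with_no_gaps(self):
        cfg = small_cfg()
        reg = generate_city_registry(cfg)
        obs = generate_observed_series(reg, cfg)
        deaths = obs["deaths"].to_numpy()
        assert (deaths >= 0).all() and np.array_equal(deaths, deaths.astype(int))
        per_city = obs.groupby("city_id").size().unique()
        assert list(per_city) == [len(period_dates(cfg.years_hist))]


class TestModelFields:
    def test_identity_injection(self):
        """With no bias and no member noise, daily MDA8 extracted from the
        hourly field reproduces the observed series."""
        cfg = small_cfg(bias_profile="none", member_noise_sd=0.0)
        reg = generate_city_registry(cfg)
        obs = generate_observed_series(reg, cfg)
        field = field_for(reg, cfg, "model_0", "r1", "historical", "present")
        got = extract_city_series(field, reg)
        merged = obs.merge(got, on=["city_id", "date"], suffixes=("_obs", "_mod"))
        assert len(merged) == len(obs)
        np.testing.assert_allclose(merged["o3_mda8_ugm3_mod"],
                                   merged["o3_mda8_ugm3_obs"], atol=1e-9)

    def test_shift_bias_recovered_in_mean(self):
        cfg = small_cfg(bias_profile="shift", bias_shift=5.0, member_noise_sd=0.0)
        reg = generate_city_registry(cfg)
        obs = generate_observed_series(reg, cfg)
        field = field_for(reg, cfg, "model_0", "r1", "historical", "present")
        got = extract_city_series(field, reg)
        merged = obs.merge(got, on=["city_id", "date"], suffixes=("_obs", "_mod"))
        diff = merged["o3_mda8_ugm3_mod"] - merged["o3_mda8_ugm3_obs"]
        assert diff.mean() == pytest.approx(5.0, abs=1e-6)

    def test_members_differ_but_regenerate_identically(self):
        cfg = small_cfg(members_per_model=2)
        reg = generate_city_registry(cfg)
        f1 = field_for(reg, cfg, "model_0", "r1", "historical", "present")
        f2 = field_for(reg, cfg, "model_0", "r2", "historical", "present")
        assert not np.array_equal(f1.values, f2.values)
        f1_again = field_for(reg, cfg, "model_0", "r1", "historical", "present")
        np.testing.assert_array_equal(f1.values, f1_again.values)

    def test_future_field_carries_scenario_trend(self):
        cfg = small_cfg(bias_profile="none", member_noise_sd=0.0,
                        trend_per_scenario={"ssp370": 9.0})
        reg = generate_city_registry(cfg)
        present = extract_city_series(field_for(reg, cfg, "model_0", "r1",
                                                "historical", "present"), reg)
        future = extract_city_series(field_for(reg, cfg, "model_0", "r1",
                                               "ssp370", "future"), reg)
        np.testing.assert_allclose(
            future["o3_mda8_ugm3"].to_numpy() - present["o3_mda8_ugm3"].to_numpy(),
            9.0, atol=1e-9)

    def test_unknown_bias_profile_rejected(self):
        with pytest.raises(ConfigError, match="bias_profile"):
            small_cfg(bias_profile="wavy").validate()

    def test_diurnal_shape_max_window_is_unit_after_scaling(self):
        w, mstar = diurnal_shape()
        means = [np.mean((w / mstar)[s:s + 8]) for s in range(17)]
        assert max(means) == pytest.approx(1.0, abs=1e-12)
        assert (w[:7] == 0).all()   # night hours are zero


class TestDemographicsAndErf:
    def test_present_anchor_and_passthrough(self):
        cfg = small_cfg(demog_jitter=0.0,
                        demog_by_scenario={"ssp370": (1.0, 1.5)})
        reg = generate_city_registry(cfg)
        tab = generate_demographics(reg, cfg)
        present = tab[tab.period_id == "present"]
        assert (present["delta_rate"] == 1.0).all() and (present["delta_pop"] == 1.0).all()
        future = tab[(tab.period_id == "future") & (tab.scenario_id == "ssp370")]
        assert (future["delta_pop"] == 1.5).all()

    def test_factors_vary_by_scenario_when_configured(self):
        cfg = small_cfg(scenarios=("ssp126", "ssp370"), demog_jitter=0.0,
                        trend_per_scenario={"ssp126": -8.0, "ssp370": 9.0},
                        demog_by_scenario={"ssp126": (1.3, 1.1), "ssp370": (1.5, 0.9)})
        tab = generate_demographics(generate_city_registry(cfg), cfg)
        fut = tab[tab.period_id == "future"].set_index("scenario_id")
        assert fut.loc["ssp126", "delta_pop"].iloc[0] != fut.loc["ssp370", "delta_pop"].iloc[0]

    def test_nonpositive_factors_rejected(self):
        cfg = small_cfg(demog_by_scenario={"ssp370": (-1.0, 1.0)})
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_erf_range_and_coefficient_convention(self):
        cfg = small_cfg()
        erf = generate_exposure_response(generate_city_registry(cfg), cfg)
        lo, hi = cfg.rr_range
        assert ((erf["rr_per_10ugm3"] >= lo) & (erf["rr_per_10ugm3"] <= hi)).all()
        np.testing.assert_allclose(erf["beta_per_ugm3"],
                                   np.log(erf["rr_per_10ugm3"]) / 10.0)
        assert (erf["se_beta"] > 0).all()
        assert (erf["threshold_ugm3"] == 70.0).all()


def test_fixed_seed_regenerates_observed_byte_identically():
    cfg = small_cfg()
    reg = generate_city_registry(cfg)
    a = generate_observed_series(reg, cfg)
    b = generate_observed_series(reg, cfg)
    pd.testing.assert_frame_equal(a, b)
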