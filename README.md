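# o3hia — projecting ozone-related acute excess mortality

`o3hia` is a research pipeline for projecting how the short-term mortality
burden of ground-level ozone in cities changes between a present and a
future climate period.  It is aimed at environmental epidemiologists and
health impact assessors who work with chemistry-climate model output
(e.g. CMIP6-style hourly surface ozone under SSP scenarios) and city-level
observational networks of daily ozone and death counts.

## The method

The pipeline follows the causal chain from simulated concentrations to
attributable deaths:

1. **Exposure metric.** Hourly gridded surface ozone is reduced to the
   city-level maximum daily 8-h average (MDA8): the largest 8-hour running
   mean whose start hour falls within the calendar day.  Mixing ratios are
   converted with 1 ppb = 1.96 µg/m³.  Each city takes the series of the
   grid cell containing its coordinates.
2. **Bias correction.** For each city, model and ensemble member, monthly
   empirical quantile functions of simulated MDA8 are matched against
   observations over a multi-year training window; the additive bias
   b_m(q) = Q_obs(q) − Q_mod(q) is assumed to persist in time and is applied
   to both present- and future-period simulations.  Members are averaged
   after correction.
3. **Baseline mortality.** City daily death counts M_h are scaled to each
   period with country-level change factors, M_p/f = M_h · ΔY_b · ΔPOP,
   where ΔY_b is the change in annual baseline mortality rate and ΔPOP the
   change in population.
4. **Burden.** Daily attributable deaths follow the attributable-fraction
   model AF = 1 − exp(−β·C), ADD = M_p/f · AF, with C = max(MDA8 − 70, 0)
   µg/m³ and β the country-specific log relative risk per µg/m³ (converted
   from RR per 10 µg/m³ as log(RR)/10).  ADD is summed per year; burdens
   are computed per model and pooled as the across-model mean.
5. **Uncertainty.** Coefficients are drawn from Normal(β, se) (1,000 draws
   by default), burdens recomputed per draw and pooled across models;
   empirical quantiles give the confidence interval.  The interval on the
   present→future change subtracts the present mean from the future bounds.
6. **Drivers.** The change in burden is decomposed exactly into
   emissions/climate, population-size, and mortality-rate components by
   first evaluating the future-ozone burden under fixed demography and then
   exploiting the burden's multiplicative dependence on ΔPOP and ΔY_b.

A synthetic-data module generates every input — city registry, observed
series, hourly gridded fields with injected biases and scenario trends,
demographic factors and exposure-response functions — with the statistical
structure the analysis assumes, so the entire chain is testable offline.
See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from o3hia import SyntheticWorldConfig, build_world, run_world, RunSettings

cfg = SyntheticWorldConfig(n_cities=8, n_countries=3, n_models=2, seed=42)
world = build_world(cfg)
result = run_world(world, RunSettings(seed=42, n_draws=1000))

totals = result.totals.set_index(["scenario_id", "period_id"])
present = totals.loc[("historical", "present")]
print(f"present burden: {present['deaths_per_year']:.1f} deaths/year "
      f"(95% eCI {present['eci_low']:.1f}-{present['eci_high']:.1f}), "
      f"AF {100 * present['af_total']:.3f}% of total deaths")
for scen in cfg.scenarios:
    ch = result.changes.set_index("scenario_id").loc[scen]
    print(f"{scen}: change {ch['delta_deaths_per_year']:+.1f} deaths/year "
          f"({ch['pct_change']:+.1f}%), CI ({ch['ci_low']:.1f}, {ch['ci_high']:.1f})")
```

prints

```
present burden: 136.5 deaths/year (95% eCI 97.1-175.8), AF 0.155% of total deaths
ssp126: change -16.3 deaths/year (-12.0%), CI (-50.4, 19.4)
ssp245: change +111.2 deaths/year (+81.5%), CI (39.2, 183.7)
ssp370: change +186.8 deaths/year (+136.9%), CI (95.1, 279.9)
ssp585: change +113.7 deaths/year (+83.3%), CI (40.1, 187.5)
```

Across these 8 synthetic cities, ozone above the 70 µg/m³ background
threshold accounts for ~0.16% of all deaths in the present period.  Under
the strong-mitigation pathway (falling ozone) the burden declines despite
population ageing; under the weak-mitigation pathways it roughly doubles,
driven jointly by rising ozone and rising baseline mortality rates.
`result.burdens`, `result.totals` and `result.decomposition` carry the full
city-, model- and driver-level tables.

A command-line interface mirrors the stages
(`o3hia simulate|bias-correct|assess|decompose|report --config run.yaml`);
`simulate` writes a complete synthetic input set (CSV tables plus NetCDF
fields) that the other commands consume.

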