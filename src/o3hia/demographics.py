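"""Demographic scaling of baseline mortality between periods.

City-level daily baseline mortality counts for a projection period are the
historical daily counts multiplied by two country-level ratios: the change
in annual baseline mortality rate and the change in population,

    M_period = M_hist * delta_rate * delta_pop.

Scaled counts are kept as real numbers; re-rounding to integers would bias
small cities, and the attributable-fraction arithmetic downstream is
continuous.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ComputationError, DataFormatError, O3HIAError

__all__ = ["scale_baseline_mortality", "compute_change_factors", "lookup_factors"]

FACTOR_COLUMNS = ["country_id", "scenario_id", "period_id", "delta_rate", "delta_pop"]


def lookup_factors(
    factors: pd.DataFrame, country_id: str, scenario_id: str, period_id: str
) -> tuple[float, float]:
    """(delta_rate, delta_pop) for one country/scenario/period, validated."""
    rows = factors[(factors["country_id"] == country_id)
                   & (factors["scenario_id"] == scenario_id)
                   & (factors["period_id"] == period_id)]
    if len(rows) != 1:
        raise O3HIAError(
            f"expected one factor row for country={country_id!r} scenario={scenario_id!r} "
            f"period={period_id!r}, found {len(rows)}")
    dy = float(rows["delta_rate"].iloc[0])
    dp = float(rows["delta_pop"].iloc[0])
    if not (np.isfinite(dy) and np.isfinite(dp) and dy > 0 and dp > 0):
        raise DataFormatError(
            f"demographic factors must be finite and positive, got ({dy}, {dp})")
    return dy, dp


def scale_baseline_mortality(
    mortality: pd.DataFrame,
    factors: pd.DataFrame,
    registry: pd.DataFrame,
    scenario_id: str,
    period_id: str,
) -> pd.DataFrame:
    """Scale a tidy (city_id, date, deaths) table to a projection period.

    Every city's daily counts are multiplied by its country's
    delta_rate * delta_pop for the given scenario and period; dates are
    unchanged.  A missing factor row raises naming the lookup keys.
    """
    country_of = dict(zip(registry["city_id"], registry["country_id"]))
    out = mortality.copy()
    scale = np.empty(len(out), dtype=float)
    for city_id, idx in out.groupby("city_id").indices.items():
        dy, dp = lookup_factors(factors, country_of[city_id], scenario_id, period_id)
        scale[idx] = dy * dp
    out["deaths"] = out["deaths"].to_numpy(dtype=float) * scale
    return out


def compute_change_factors(
    historical: pd.DataFrame,
    projection: pd.DataFrame,
    period_id: str = "future",
) -> pd.DataFrame:
    """Country-level change factors from historical and projected tables.

    ``historical`` has columns (country_id, mortality_rate, population);
    ``projection`` additionally carries scenario_id.  delta_rate and
    delta_pop are simple ratios of projected to historical values.
    """
    hist = historical.set_index("country_id")
    rows = []
    for r in projection.itertuples(index=False):
        if r.country_id not in hist.index:
            raise ComputationError(f"no historical row for country {r.country_id!r}")
        h = hist.loc[r.country_id]
        if h["mortality_rate"] <= 0 or h["population"] <= 0:
            raise ComputationError(
                f"non-positive historical denominator for country {r.country_id!r}")
        rows.append((r.country_id, r.scenario_id, period_id,
                     float(r.mortality_rate) / float(h["mortality_rate"]),
                     float(r.population) / float(h["population"])))
    return pd.DataFrame(rows, columns=FACTOR_COLUMNS)
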