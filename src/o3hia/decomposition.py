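"""Driver decomposition of the change in attributable mortality.

The present-to-future change in burden is allocated to three drivers with
a sequential scheme: emissions and climate are isolated first by evaluating
the future-ozone burden under fixed (present-period) demography; because
the burden is multiplicatively proportional to the population and
mortality-rate factors, the remaining change splits exactly between
population size (applied next) and mortality rates (applied last, and
therefore carrying the population-rate interaction).

With B_fp the future-ozone burden under present demography and
r_pop = dPOP_f / dPOP_p, r_rate = dY_f / dY_p the future-to-present factor
ratios:

    climate    = B_fp - B_present
    population = B_fp * (r_pop - 1)
    rates      = B_fp * r_pop * (r_rate - 1)

and the three components sum exactly to B_future - B_present.  Percent
contributions are reported relative to the present-period burden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ComputationError

__all__ = ["DriverComponents", "decompose_drivers"]


@dataclass
class DriverComponents:
    unit_id: str
    scenario_id: str
    climate: float
    population: float
    rate: float
    total: float
    pct_climate: float
    pct_population: float
    pct_rate: float
    pct_total: float


def decompose_drivers(
    present_burden: float,
    future_burden: float,
    *,
    present_factors: tuple[float, float] = (1.0, 1.0),
    future_factors: tuple[float, float] = (1.0, 1.0),
    unit_id: str = "total",
    scenario_id: str = "",
) -> DriverComponents:
    """Allocate the burden change to climate/emissions, population, rates.

    ``present_factors`` and ``future_factors`` are the (delta_rate,
    delta_pop) demographic scalings applied to the historical baseline in
    each period.  The rate component is computed as the exact remainder so
    additivity holds to the last bit.
    """
    dy_p, dpop_p = present_factors
    dy_f, dpop_f = future_factors
    if min(dy_p, dpop_p, dy_f, dpop_f) <= 0:
        raise ComputationError("demographic factors must be positive")

    # Future-ozone burden under present demography: the burden scales
    # multiplicatively with delta_rate * delta_pop.
    b_fp = future_burden * (dy_p * dpop_p) / (dy_f * dpop_f)
    r_pop = dpop_f / dpop_p

    climate = b_fp - present_burden
    population = b_fp * (r_pop - 1.0)
    total = future_burden - present_burden
    rate = total - climate - population   # == b_fp * r_pop * (r_rate - 1)

    def pct(x: float) -> float:
        return 100.0 * x / present_burden if present_burden != 0 else math.nan

    return DriverComponents(
        unit_id=unit_id, scenario_id=scenario_id,
        climate=climate, population=population, rate=rate, total=total,
        pct_climate=pct(climate), pct_population=pct(population),
        pct_rate=pct(rate), pct_total=pct(total))
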