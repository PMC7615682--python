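"""Attributable-fraction health impact assessment.

Daily excess mortality attributable to short-term ozone exposure above a
background threshold is computed with the attributable-fraction model

    AF = 1 - exp(-beta * C),        C = max(MDA8 - threshold, 0),
    ADD = M * AF,

where beta is the log relative risk of death per ug/m3 of MDA8 ozone above
the threshold (converted from the conventional relative risk per
10 ug/m3 as log(RR)/10), M is the scaled daily baseline death count, and
ADD the attributable daily deaths.  Annual burdens sum ADD over the period
and divide by the number of years; the attributable fraction of total
deaths divides by the summed baseline deaths.  Days below the threshold
contribute AF = 0 rather than being dropped, so total-death denominators
are unaffected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ComputationError

__all__ = [
    "ExposureResponse",
    "MortalityEstimate",
    "PeriodChange",
    "excess_concentration",
    "attributable_fraction",
    "daily_attributable_deaths",
    "annual_burden",
    "annual_burden_for_betas",
    "compare_periods",
    "pool_models",
    "beta_from_rr10",
]


@dataclass
class ExposureResponse:
    """Country/region-level exposure-response function.

    beta is the log relative risk per ug/m3 above the threshold;
    se_beta its standard error; threshold the background concentration
    (default 70 ug/m3) below which no burden is attributed.
    """

    country_id: str
    beta: float
    se_beta: float
    threshold: float = 70.0

    def __post_init__(self):
        if self.se_beta < 0:
            raise ComputationError("se_beta must be non-negative")
        if self.threshold < 0:
            raise ComputationError("threshold must be non-negative")


@dataclass
class MortalityEstimate:
    unit_id: str
    scenario_id: str
    period_id: str
    model_id: str
    deaths_per_year: float
    af_total: float
    eci_low: float = math.nan
    eci_high: float = math.nan


@dataclass
class PeriodChange:
    delta: float
    pct: float
    pct_defined: bool = True


def beta_from_rr10(rr_per_10: float) -> float:
    """Log relative risk per ug/m3 from a relative risk per 10 ug/m3."""
    if rr_per_10 <= 0:
        raise ComputationError("relative risk must be positive")
    return math.log(rr_per_10) / 10.0


def excess_concentration(conc, threshold: float = 70.0):
    """Concentration above the background threshold, clamped at zero."""
    return np.maximum(np.asarray(conc, dtype=float) - threshold, 0.0)


def attributable_fraction(beta, conc_excess):
    """AF = 1 - exp(-beta * C); lies in [0, 1) for beta >= 0, C >= 0."""
    out = 1.0 - np.exp(-np.asarray(beta, dtype=float) * np.asarray(conc_excess, dtype=float))
    if np.ndim(out) == 0:
        return float(out)
    return out


def daily_attributable_deaths(deaths, af):
    """ADD = scaled daily baseline deaths times the attributable fraction."""
    out = np.asarray(deaths, dtype=float) * np.asarray(af, dtype=float)
    if np.ndim(out) == 0:
        return float(out)
    return out


def annual_burden(
    add: pd.Series,
    total_deaths: pd.Series,
    *,
    n_years: float | None = None,
    conc: pd.Series | None = None,
    guideline: float | None = None,
) -> tuple[float, float]:
    """(attributable deaths/year, attributable fraction of total deaths).

    ``add`` and ``total_deaths`` are daily series over the same period.  If
    ``guideline`` is given, ADD is summed only over days whose concentration
    (``conc``, same index) exceeds it; the total-death denominator is
    unaffected.  ``n_years`` defaults to the number of distinct calendar
    years covered.
    """
    if len(add) == 0:
        raise ComputationError("empty attributable-deaths series")
    if n_years is None:
        n_years = add.index.year.nunique()
    if guideline is not None:
        if conc is None:
            raise ComputationError("guideline filtering requires the concentration series")
        total_add = float(add[np.asarray(conc, dtype=float) > guideline].sum())
    else:
        total_add = float(add.sum())
    denom = float(np.asarray(total_deaths, dtype=float).sum())
    if denom <= 0:
        raise ComputationError("total deaths over the period must be positive")
    return total_add / float(n_years), total_add / denom


def annual_burden_for_betas(
    conc: np.ndarray,
    deaths: np.ndarray,
    betas: np.ndarray,
    *,
    threshold: float = 70.0,
    n_years: float = 1.0,
    guideline: float | None = None,
) -> np.ndarray:
    """Vectorised deaths/year for many coefficient values at once.

    Used by the Monte Carlo uncertainty machinery: for each beta, the
    burden is sum_d deaths_d * (1 - exp(-beta * C_d)) / n_years.  Negative
    betas are evaluated as-is (yielding negative contributions) so that
    empirical confidence intervals can cross zero.
    """
    c = excess_concentration(conc, threshold)
    d = np.asarray(deaths, dtype=float)
    if guideline is not None:
        keep = np.asarray(conc, dtype=float) > guideline
        c = c[keep]
        d = d[keep]
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    af = 1.0 - np.exp(-np.outer(c, betas))       # (n_days, n_betas)
    return d @ af / float(n_years)


def compare_periods(present: float, future: float) -> PeriodChange:
    """Absolute and percent change between matched period estimates."""
    delta = future - present
    if present == 0:
        return PeriodChange(delta=delta, pct=math.nan, pct_defined=False)
    return PeriodChange(delta=delta, pct=100.0 * delta / present)


def pool_models(estimates) -> tuple[float, tuple[float, float]]:
    """Pooled point estimate (mean across models) and the model range."""
    values = np.asarray(list(estimates), dtype=float)
    if values.size == 0:
        raise ComputationError("no model estimates to pool")
    return float(values.mean()), (float(values.min()), float(values.max()))
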