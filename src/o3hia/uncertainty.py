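"""Monte Carlo empirical confidence intervals for attributable mortality.

Coefficient uncertainty is propagated by drawing exposure-response
coefficients from Normal(beta, se_beta) (1,000 draws by default),
recomputing the burden per draw, and taking empirical quantiles of the
resulting distribution.  Inter-model variability enters by pooling the
draw-level burdens of all chemistry-climate models into one empirical
distribution before taking quantiles.

For the change between periods the interval follows the rule of
subtracting the present-period mean estimate from the future-period lower
and upper bounds, so the change interval has the width of the future one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComputationError, ConfigError
from .hia import ExposureResponse

__all__ = ["CoefficientDraws", "sample_coefficients", "empirical_ci", "change_ci"]


@dataclass
class CoefficientDraws:
    country_id: str
    draws: np.ndarray
    seed: int
    n_draws: int


def sample_coefficients(
    erf: ExposureResponse, n_draws: int = 1000, seed: int = 0
) -> CoefficientDraws:
    """Draw coefficient samples from Normal(beta, se_beta), seeded.

    With se_beta = 0 the distribution is degenerate and every draw equals
    beta.  Negative draws are retained: the attributable-fraction model is
    evaluated at the raw coefficient so that interval bounds can reach or
    cross zero.
    """
    if n_draws < 2:
        raise ConfigError("n_draws must be at least 2")
    rng = np.random.default_rng(seed)
    draws = rng.normal(erf.beta, erf.se_beta, size=int(n_draws))
    return CoefficientDraws(country_id=erf.country_id, draws=draws,
                            seed=seed, n_draws=int(n_draws))


def empirical_ci(draws, level: float = 95.0) -> tuple[float, float]:
    """Empirical quantile interval of a Monte Carlo burden distribution.

    ``draws`` are burden values pooled across all models' coefficient
    samples; the bounds are the (1-level)/2 and 1-(1-level)/2 empirical
    quantiles.
    """
    arr = np.asarray(draws, dtype=float).ravel()
    if arr.size == 0:
        raise ComputationError("empty draw distribution")
    alpha = 1.0 - level / 100.0
    lo, hi = np.quantile(arr, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def change_ci(present_mean: float, future_ci: tuple[float, float]) -> tuple[float, float]:
    """Interval for the present-to-future change in burden.

    Computed as (future_low - present_mean, future_high - present_mean);
    translation-invariant, with width equal to the future interval's.
    """
    lo, hi = future_ci
    if lo > hi:
        raise ComputationError("future confidence interval bounds are unordered")
    return lo - present_mean, hi - present_mean
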