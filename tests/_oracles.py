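"""Independent brute-force oracles used to validate the optimized paths."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def mda8_brute(hourly: pd.Series, min_window_hours: int = 6,
               min_valid_windows: int = 18) -> pd.Series:
    """Exhaustive enumeration of all 24 start-hour 8-h windows per day."""
    lookup = {ts: v for ts, v in hourly.items()}
    days = sorted({ts.normalize() for ts in hourly.index})
    out = {}
    for day in days:
        best = -math.inf
        n_valid = 0
        for start in range(24):
            vals = []
            for k in range(8):
                v = lookup.get(day + pd.Timedelta(hours=start + k))
                if v is not None and not (isinstance(v, float) and math.isnan(v)):
                    vals.append(v)
            if len(vals) >= min_window_hours:
                n_valid += 1
                best = max(best, sum(vals) / len(vals))
        if n_valid >= min_valid_windows:
            out[day] = best
    return pd.Series(out, dtype=float)


def direct_burden(conc: np.ndarray, daily_deaths: np.ndarray, beta: float,
                  threshold: float, n_years: float,
                  delta_rate: float = 1.0, delta_pop: float = 1.0) -> float:
    """Plain evaluation of the scaling/attributable-fraction/summation chain."""
    total = 0.0
    for c, m in zip(conc, daily_deaths):
        excess = c - threshold if c > threshold else 0.0
        af = 1.0 - math.exp(-beta * excess)
        total += m * delta_rate * delta_pop * af
    return total / n_years
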