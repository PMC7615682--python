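"""Monthly per-quantile bias correction of model MDA8 ozone against observations.

For every city x model (x ensemble member), the empirical quantile functions
of observed and simulated MDA8 are evaluated per calendar month on a dense
probability grid over a common training window; the additive bias
(observed minus model quantile) is stored and assumed to persist in time,
so the same map corrects both present-period and future-period simulations.

Probability assignment for a new value uses the interpolated empirical CDF
of the month's training model distribution, with constant bias extension
beyond the training range.  The fitting grid is augmented with the training
sample's own plotting positions i/(n-1) so that the corrected training
distribution interpolates the observed monthly quantiles exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, BiasApplicationError, FittingError

logger = logging.getLogger(__name__)

__all__ = [
    "MonthlyBias",
    "QuantileBiasMap",
    "fit_quantile_bias",
    "apply_quantile_bias",
    "fit_bias_maps",
    "apply_bias_maps",
    "summarize_bias",
    "bias_map_to_frame",
    "bias_map_from_frame",
]


@dataclass
class MonthlyBias:
    """Quantile grid, model quantiles and additive bias for one calendar month."""

    probs: np.ndarray      # strictly increasing probabilities in [0, 1]
    model_q: np.ndarray    # training model quantile function on the grid (ug/m3)
    bias: np.ndarray       # observed quantile - model quantile (ug/m3)


@dataclass
class QuantileBiasMap:
    city_id: str
    model_id: str
    months: dict[int, MonthlyBias] = field(default_factory=dict)


def fit_quantile_bias(
    observed: pd.Series,
    model_hist: pd.Series,
    *,
    grid_size: int = 101,
    min_month_n: int = 30,
    city_id: str = "",
    model_id: str = "",
) -> QuantileBiasMap:
    """Fit a monthly quantile-bias map from paired observed/model daily series.

    Both series are daily MDA8 in ug/m3 indexed by date; only dates present
    in both enter the fit.  Days are pooled by calendar month across the
    training years (Feb 29 pools into February).  Months with fewer than
    ``min_month_n`` paired days raise :class:`FittingError`.
    """
    joined = pd.DataFrame({"obs": observed, "mod": model_hist}).dropna()
    if joined.empty:
        raise AlignmentError(f"city {city_id!r}: observed and model series share no dates")
    base = np.linspace(0.0, 1.0, int(grid_size))
    months: dict[int, MonthlyBias] = {}
    for m, grp in joined.groupby(joined.index.month):
        o = grp["obs"].to_numpy(dtype=float)
        v = grp["mod"].to_numpy(dtype=float)
        if len(v) < min_month_n:
            raise FittingError(
                f"city {city_id!r} month {m}: only {len(v)} paired days (need {min_month_n})")
        # Augment the grid with the sample plotting positions so that the
        # fitted map reproduces the training quantiles exactly.
        probs = np.union1d(base, np.linspace(0.0, 1.0, len(v)))
        q_mod = np.quantile(v, probs)
        q_obs = np.quantile(o, probs)
        months[int(m)] = MonthlyBias(probs=probs, model_q=q_mod, bias=q_obs - q_mod)
    return QuantileBiasMap(city_id=city_id, model_id=model_id, months=months)


def apply_quantile_bias(bias_map: QuantileBiasMap, model_series: pd.Series) -> pd.Series:
    """Correct a model daily series with a fitted monthly quantile-bias map.

    Each value is assigned a probability via the interpolated empirical CDF
    of its month's training model distribution (values beyond the training
    range get p = 0 or 1, i.e. constant bias extension), then shifted by the
    interpolated bias at that probability.  Corrected values are clipped at
    zero; the clip count is logged.
    """
    values = model_series.to_numpy(dtype=float)
    months = model_series.index.month
    out = np.empty_like(values)
    for m in np.unique(months):
        mb = bias_map.months.get(int(m))
        if mb is None:
            raise BiasApplicationError(
                f"city {bias_map.city_id!r}: no fitted bias map for month {m}")
        mask = months == m
        v = values[mask]
        p = np.interp(v, mb.model_q, mb.probs)
        corrected = v + np.interp(p, mb.probs, mb.bias)
        # The additive map is monotone whenever the observed quantile
        # function is nondecreasing; detect and log any violation.
        order = np.argsort(v, kind="stable")
        if np.any(np.diff(corrected[order]) < -1e-9):
            logger.warning("apply_quantile_bias: rank order violated for city %r month %d",
                           bias_map.city_id, m)
        out[mask] = corrected
    n_clipped = int((out < 0).sum())
    if n_clipped:
        logger.info("apply_quantile_bias: clipped %d negative corrected value(s) to 0 (city %r)",
                    n_clipped, bias_map.city_id)
    np.maximum(out, 0.0, out=out)
    return pd.Series(out, index=model_series.index, name=model_series.name)


def _city_series(df: pd.DataFrame, city_id: str, column: str) -> pd.Series:
    sub = df[df["city_id"] == city_id]
    return pd.Series(sub[column].to_numpy(dtype=float), index=pd.DatetimeIndex(sub["date"]))


def fit_bias_maps(
    observed: pd.DataFrame,
    model_hist: pd.DataFrame,
    *,
    grid_size: int = 101,
    min_month_n: int = 30,
    model_id: str = "",
) -> dict[str, QuantileBiasMap]:
    """Fit per-city bias maps from tidy (city_id, date, o3_mda8_ugm3) tables."""
    maps = {}
    for city_id in observed["city_id"].unique():
        maps[city_id] = fit_quantile_bias(
            _city_series(observed, city_id, "o3_mda8_ugm3"),
            _city_series(model_hist, city_id, "o3_mda8_ugm3"),
            grid_size=grid_size, min_month_n=min_month_n,
            city_id=city_id, model_id=model_id)
    return maps


def apply_bias_maps(maps: dict[str, QuantileBiasMap], model_series: pd.DataFrame) -> pd.DataFrame:
    """Apply per-city maps to a tidy model series table."""
    frames = []
    for city_id, bias_map in maps.items():
        series = _city_series(model_series, city_id, "o3_mda8_ugm3")
        corrected = apply_quantile_bias(bias_map, series)
        frames.append(pd.DataFrame({
            "city_id": city_id, "date": corrected.index,
            "o3_mda8_ugm3": corrected.to_numpy()}))
    return pd.concat(frames, ignore_index=True)


def summarize_bias(observed: pd.DataFrame, model: pd.DataFrame) -> pd.DataFrame:
    """Mean/min/max of (model - observed) per city plus a pooled row.

    The report is antisymmetric under swapping the two arguments.
    """
    merged = observed.merge(model, on=["city_id", "date"], suffixes=("_obs", "_mod"))
    if merged.empty:
        raise AlignmentError("observed and model tables share no (city, date) pairs")
    diff = merged["o3_mda8_ugm3_mod"] - merged["o3_mda8_ugm3_obs"]
    per_city = (pd.DataFrame({"city_id": merged["city_id"], "bias": diff})
                .groupby("city_id")["bias"].agg(["mean", "min", "max"]).reset_index())
    pooled = pd.DataFrame([{"city_id": "(pooled)", "mean": diff.mean(),
                            "min": diff.min(), "max": diff.max()}])
    return pd.concat([per_city, pooled], ignore_index=True)


def bias_map_to_frame(maps: dict[str, QuantileBiasMap]) -> pd.DataFrame:
    """Serialize fitted maps to a tidy frame for inspection / round-trips."""
    rows = []
    for city_id in sorted(maps):
        bm = maps[city_id]
        for m in sorted(bm.months):
            mb = bm.months[m]
            for p, q, b in zip(mb.probs, mb.model_q, mb.bias):
                rows.append((bm.city_id, bm.model_id, m, p, q, b))
    return pd.DataFrame(rows, columns=["city_id", "model_id", "month",
                                       "prob", "model_q_ugm3", "bias_ugm3"])


def bias_map_from_frame(frame: pd.DataFrame) -> dict[str, QuantileBiasMap]:
    maps: dict[str, QuantileBiasMap] = {}
    for (city_id, model_id), grp in frame.groupby(["city_id", "model_id"]):
        bm = QuantileBiasMap(city_id=city_id, model_id=model_id)
        for m, sub in grp.groupby("month"):
            sub = sub.sort_values("prob")
            bm.months[int(m)] = MonthlyBias(
                probs=sub["prob"].to_numpy(dtype=float),
                model_q=sub["model_q_ugm3"].to_numpy(dtype=float),
                bias=sub["bias_ugm3"].to_numpy(dtype=float))
        maps[city_id] = bm
    return maps
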