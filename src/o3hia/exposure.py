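"""City-level daily ozone exposure from hourly gridded fields.

The exposure metric throughout the package is the maximum daily 8-h average
(MDA8) ozone concentration: the largest 8-hour running mean of hourly ozone
whose start hour lies within the calendar day.  Windows may extend into the
next day; a window is valid when at least ``min_window_hours`` of its 8
hours are present, and a day is reported when at least ``min_valid_windows``
of its 24 candidate windows are valid.

Concentrations are carried in micrograms per cubic metre.  Model fields in
molar mixing-ratio units are converted with a constant factor of
1 ppb = 1.96 ug/m3, the standard surface-conditions scaling for ozone.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from numpy.lib.stride_tricks import sliding_window_view

from .errors import AlignmentError, CityLookupError, DataFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "PPB_TO_UGM3",
    "ppb_to_ugm3",
    "mda8_from_hourly",
    "locate_cell",
    "extract_city_series",
    "average_members",
]

#: Mass-density equivalent of a 1 ppb ozone mixing ratio at surface conditions.
PPB_TO_UGM3 = 1.96


def ppb_to_ugm3(values):
    """Convert an ozone mixing ratio in ppb to a mass density in ug/m3.

    Vectorised over array-likes; negative mixing ratios are rejected.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise DataFormatError("negative mixing ratio passed to ppb_to_ugm3")
    out = arr * PPB_TO_UGM3
    if np.isscalar(values) or np.ndim(values) == 0:
        return float(out)
    return out


def _validate_hourly_index(idx: pd.DatetimeIndex) -> None:
    if not isinstance(idx, pd.DatetimeIndex):
        raise DataFormatError("hourly series must be indexed by timestamps")
    if len(idx) == 0:
        raise DataFormatError("hourly series is empty")
    if not idx.is_monotonic_increasing or idx.has_duplicates:
        raise DataFormatError("hourly timestamps must be strictly increasing")
    if (idx != idx.floor("h")).any():
        raise DataFormatError("non-hourly spacing: timestamps must fall on whole hours")


def mda8_from_hourly(
    hourly: pd.Series,
    *,
    min_window_hours: int = 6,
    min_valid_windows: int = 18,
) -> pd.Series:
    """Reduce an hourly concentration series to daily MDA8 values.

    Parameters
    ----------
    hourly
        Concentrations indexed by hourly timestamps.  Missing hours may be
        absent from the index or present as NaN; both count as missing.
    min_window_hours
        Minimum present hours for an 8-h window mean to be valid.
    min_valid_windows
        Minimum valid windows (out of 24 start hours) for a day to be
        reported; days falling short are omitted with a logged warning.

    Returns
    -------
    pandas.Series
        MDA8 per reported calendar day, indexed by normalized date.
    """
    _validate_hourly_index(hourly.index)
    start = hourly.index[0].normalize()
    end = hourly.index[-1].normalize()
    n_days = (end - start).days + 1
    # Pad 7 hours past the last day so late-start windows can be evaluated.
    full = pd.date_range(start, periods=n_days * 24 + 7, freq="h")
    arr = hourly.reindex(full).to_numpy(dtype=float)

    windows = sliding_window_view(arr, 8)[: n_days * 24]
    counts = (~np.isnan(windows)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        sums = np.nansum(windows, axis=1)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    valid = counts >= min_window_hours
    means = np.where(valid, means, np.nan)

    day_means = means.reshape(n_days, 24)
    day_valid = valid.reshape(n_days, 24)
    n_valid = day_valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mda8 = np.where(n_valid > 0, np.nanmax(np.where(day_valid, day_means, -np.inf), axis=1), np.nan)
    keep = n_valid >= min_valid_windows

    dates = pd.date_range(start, periods=n_days, freq="D")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("mda8_from_hourly: omitted %d day(s) with fewer than %d valid windows",
                       n_dropped, min_valid_windows)
    return pd.Series(mda8[keep], index=dates[keep], name="o3_mda8_ugm3")


def locate_cell(centers: np.ndarray, coord: float, what: str = "coordinate") -> int:
    """Index of the regular-grid cell whose bounds contain ``coord``.

    Cell i spans [center_i - res/2, center_i + res/2); a point exactly on a
    shared boundary is assigned to the lower-index cell.  Points outside the
    grid extent raise :class:`CityLookupError`.
    """
    centers = np.asarray(centers, dtype=float)
    if len(centers) == 1:
        res = 1.0
    else:
        steps = np.diff(centers)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise DataFormatError("grid coordinates must be regular and increasing")
        res = float(steps[0])
    edges = np.concatenate([[centers[0] - res / 2], centers + res / 2])
    if coord < edges[0] or coord > edges[-1]:
        raise CityLookupError(f"{what} {coord} outside grid extent [{edges[0]}, {edges[-1]}]")
    i = int(np.searchsorted(edges, coord, side="left")) - 1
    return min(max(i, 0), len(centers) - 1)


def _field_dataarray(field) -> xr.DataArray:
    if isinstance(field, xr.Dataset):
        if "o3" not in field:
            raise DataFormatError("gridded field dataset must contain an 'o3' variable")
        field = field["o3"]
    if "units" not in field.attrs:
        raise DataFormatError("gridded field lacks a 'units' attribute (expected 'ppb' or 'ugm3')")
    if field.attrs["units"] not in ("ppb", "ugm3"):
        raise DataFormatError(f"unknown units tag {field.attrs['units']!r}")
    return field


def extract_city_series(
    field,
    registry: pd.DataFrame,
    *,
    min_window_hours: int = 6,
    min_valid_windows: int = 18,
) -> pd.DataFrame:
    """Daily MDA8 series (ug/m3) for every registry city from a gridded field.

    Each city receives the hourly series of the grid cell containing its
    coordinates (no interpolation), converted to ug/m3 if the field is in
    ppb, then reduced with :func:`mda8_from_hourly`.
    """
    da = _field_dataarray(field)
    values = da.transpose("time", "lat", "lon").values
    time = pd.DatetimeIndex(da["time"].values)
    lat_c = np.asarray(da["lat"].values, dtype=float)
    lon_c = np.asarray(da["lon"].values, dtype=float)
    in_ppb = da.attrs["units"] == "ppb"

    frames = []
    for row in registry.itertuples(index=False):
        try:
            i = locate_cell(lat_c, float(row.lat), "latitude")
            j = locate_cell(lon_c, float(row.lon), "longitude")
        except CityLookupError as exc:
            raise CityLookupError(f"city {row.city_id}: {exc}") from exc
        series = pd.Series(values[:, i, j], index=time)
        if in_ppb:
            series = series * PPB_TO_UGM3
        daily = mda8_from_hourly(series, min_window_hours=min_window_hours,
                                 min_valid_windows=min_valid_windows)
        frames.append(pd.DataFrame({
            "city_id": row.city_id,
            "date": daily.index,
            "o3_mda8_ugm3": daily.to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)


def average_members(series_list: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Arithmetic mean of bias-corrected daily series across ensemble members.

    Members must share identical (city_id, date) coverage; averaging is
    performed after each member has been bias-corrected individually.
    """
    if not series_list:
        raise AlignmentError("no member series to average")
    ref = series_list[0].sort_values(["city_id", "date"]).reset_index(drop=True)
    keys = list(zip(ref["city_id"], ref["date"]))
    acc = ref["o3_mda8_ugm3"].to_numpy(dtype=float).copy()
    for other in series_list[1:]:
        o = other.sort_values(["city_id", "date"]).reset_index(drop=True)
        if list(zip(o["city_id"], o["date"])) != keys:
            raise AlignmentError("ensemble members have mismatched city/date coverage")
        acc += o["o3_mda8_ugm3"].to_numpy(dtype=float)
    out = ref.copy()
    out["o3_mda8_ugm3"] = acc / len(series_list)
    return out
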