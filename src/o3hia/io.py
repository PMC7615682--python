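"""File formats and run configuration.

All tables are plain CSV with ISO-8601 dates; gridded ozone fields are
NetCDF with dims (time, lat, lon), a single ``o3`` variable, and a
mandatory ``units`` attribute ("ppb" or "ugm3").  Write-then-read
round-trips reproduce values to full precision; schema violations raise
:class:`DataFormatError` naming the offending file and column.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import xarray as xr
import yaml

from .errors import ConfigError, DataFormatError
from .pipeline import RunSettings
from .synthetic_data import SyntheticWorldConfig

__all__ = [
    "RunConfig", "load_config", "save_config",
    "write_city_series", "read_city_series",
    "write_registry", "read_registry",
    "write_factors", "read_factors",
    "write_erf", "read_erf",
    "write_field", "read_field",
    "field_filename",
]

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Top-level YAML-backed run configuration.

    ``world`` configures the synthetic generator (``o3hia simulate``);
    ``settings`` the analysis stages; ``input_dir``/``output_dir`` where
    simulated inputs live and results are written.
    """

    world: SyntheticWorldConfig = field(default_factory=SyntheticWorldConfig)
    settings: RunSettings = field(default_factory=RunSettings)
    input_dir: str = "inputs"
    output_dir: str = "results"

    def validate(self) -> None:
        self.world.validate()
        self.settings.validate()


def _as_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_as_plain(v) for v in obj]
    return obj


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_as_plain(config), sort_keys=False))


def _coerce(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if isinstance(v, list) and isinstance(v[0] if v else None, list):
            v = tuple(tuple(x) for x in v)
        elif isinstance(v, list):
            v = tuple(v)
        elif isinstance(v, dict):
            v = {kk: tuple(vv) if isinstance(vv, list) else vv for kk, vv in v.items()}
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level of the config must be a mapping")
    cfg = RunConfig(
        world=_coerce(SyntheticWorldConfig, raw.get("world", {}) or {}),
        settings=_coerce(RunSettings, raw.get("settings", {}) or {}),
        input_dir=raw.get("input_dir", "inputs"),
        output_dir=raw.get("output_dir", "results"),
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# CSV tables

def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing column(s) {missing}")


def _parse_dates(df: pd.DataFrame, path) -> pd.DataFrame:
    try:
        df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    except ValueError as exc:
        raise DataFormatError(f"{path}: dates must be ISO-8601 (YYYY-MM-DD): {exc}") from exc
    return df


def write_city_series(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_city_series(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"city_id": str})
    _require_columns(df, ["city_id", "date", "o3_mda8_ugm3"], path)
    return _parse_dates(df, path)


def write_registry(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_registry(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"city_id": str, "country_id": str})
    _require_columns(df, ["city_id", "country_id", "lat", "lon"], path)
    if df["city_id"].duplicated().any():
        raise DataFormatError(f"{path}: duplicate city_id values")
    return df


def write_factors(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_factors(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"country_id": str, "scenario_id": str, "period_id": str})
    _require_columns(df, ["country_id", "scenario_id", "period_id",
                          "delta_rate", "delta_pop"], path)
    return df


def write_erf(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_erf(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"country_id": str})
    _require_columns(df, ["country_id", "beta_per_ugm3", "se_beta", "threshold_ugm3"], path)
    return df


# ---------------------------------------------------------------------------
# gridded fields (NetCDF via the scipy backend)

def field_filename(model_id: str, member_id: str, scenario_id: str, period_id: str) -> str:
    return f"o3_{model_id}_{member_id}_{scenario_id}_{period_id}.nc"


def write_field(da: xr.DataArray, path) -> None:
    if "units" not in da.attrs:
        raise DataFormatError("refusing to write a gridded field without a units attribute")
    ds = da.to_dataset(name="o3")
    ds.to_netcdf(path, engine="scipy")


def read_field(path) -> xr.DataArray:
    ds = xr.open_dataset(path, engine="scipy")
    if "o3" not in ds:
        raise DataFormatError(f"{path}: no 'o3' variable")
    da = ds["o3"].load()
    ds.close()
    if "units" not in da.attrs:
        raise DataFormatError(f"{path}: variable 'o3' lacks a units attribute")
    if da.attrs["units"] not in ("ppb", "ugm3"):
        raise DataFormatError(f"{path}: unknown units {da.attrs['units']!r}")
    return da
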