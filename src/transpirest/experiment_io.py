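"""Data containers, CSV I/O and climate averaging for weighing experiments.

File formats
------------
Weighing log (one or more items per file), comma-separated, UTF-8, header
mandatory, ISO-8601 timestamps::

    item_id,timestamp,mass_g
    apple-01,2024-03-01T08:00:00,131.2472

Climate log::

    timestamp,temp_c,rh_pct,pbar_pa
    2024-03-01T08:00:00,20.1,49.8,101325

``pbar_pa`` is optional; when absent the standard atmosphere is substituted
downstream and the substitution is logged, because every assumption the
method leans on must be visible in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .constants import DEFAULT_WATER_ACTIVITY
from .errors import CoverageError, DataValidationError, ParseError

__all__ = [
    "WeighingSeries",
    "ClimateLog",
    "ProtocolConfig",
    "read_weighing_csv",
    "write_weighing_csv",
    "read_climate_csv",
    "write_climate_csv",
    "mean_climate",
]

logger = logging.getLogger("transpirest")

WEIGHING_COLUMNS = ("item_id", "timestamp", "mass_g")
CLIMATE_COLUMNS = ("timestamp", "temp_c", "rh_pct")


@dataclass
class WeighingSeries:
    """Ordered timestamped masses of one fruit or one bulk container."""

    item_id: str
    timestamps: pd.DatetimeIndex
    mass_g: np.ndarray
    is_bulk: bool = False
    container_tare_g: float = 0.0

    def __post_init__(self):
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.mass_g = np.asarray(self.mass_g, dtype=float)
        if len(self.timestamps) != len(self.mass_g):
            raise DataValidationError(f"{self.item_id}: timestamp/mass length mismatch")
        if len(self.timestamps) < 2:
            raise DataValidationError(
                f"{self.item_id}: a weighing series needs at least 2 records"
            )
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise DataValidationError(
                f"{self.item_id}: timestamps must be strictly increasing"
            )
        if np.any(~np.isfinite(self.mass_g)):
            raise DataValidationError(f"{self.item_id}: non-finite mass values")
        if np.any(self.mass_g - self.container_tare_g <= 0):
            raise DataValidationError(
                f"{self.item_id}: masses must be positive after tare subtraction"
            )

    @property
    def net_mass_g(self) -> np.ndarray:
        """Masses with the container tare removed."""
        return self.mass_g - self.container_tare_g

    @property
    def duration_h(self) -> float:
        return (self.timestamps[-1] - self.timestamps[0]) / pd.Timedelta(hours=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"item_id": self.item_id, "timestamp": self.timestamps, "mass_g": self.mass_g}
        )


@dataclass
class ClimateLog:
    """Timestamped air temperature, relative humidity and optional pressure."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.data.copy()
        missing = [c for c in CLIMATE_COLUMNS if c not in df.columns]
        if missing:
            raise DataValidationError(f"climate log missing columns: {missing}")
        df["timestamp"] = pd.DatetimeIndex(df["timestamp"])
        if not df["timestamp"].is_monotonic_increasing or df["timestamp"].duplicated().any():
            raise DataValidationError("climate timestamps must be strictly increasing")
        for col in ("temp_c", "rh_pct") + (("pbar_pa",) if "pbar_pa" in df else ()):
            if df[col].isna().any() or ~np.isfinite(df[col].to_numpy(float)).all():
                raise DataValidationError(f"climate log column {col!r} has non-finite values")
        if ((df["rh_pct"] < 0) | (df["rh_pct"] > 100)).any():
            raise DataValidationError("relative humidity outside [0, 100] %")
        self.data = df.reset_index(drop=True)

    @property
    def has_pressure(self) -> bool:
        return "pbar_pa" in self.data.columns

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data["timestamp"])


class ProtocolConfig(BaseModel):
    """Measurement-protocol configuration.

    ``free``   : unrestricted free convection; rT = rtot - rb_default.
    ``forced`` : airflow > 2 m/s strips the boundary layer; rtot = rT.
    ``wetted`` : water-film surface, equivalent stripping; rtot = rT.
    ``bulk``   : packed container; rB = rtot_bulk - tissue_resistance.
    """

    protocol: Literal["free", "forced", "wetted", "bulk"] = "free"
    rb_default_s_cm: float = Field(default=4.0, ge=0.0)
    aw: float = Field(default=DEFAULT_WATER_ACTIVITY, gt=0.0, le=1.0)
    estimator: Literal["endpoint", "slope"] = "endpoint"
    min_duration_h: Optional[float] = None
    tissue_resistance_s_cm: Optional[float] = Field(default=None, ge=0.0)
    pressure_default_pa: float = Field(default=101325.0, gt=0.0)

    @model_validator(mode="after")
    def _defaults(self):
        if self.min_duration_h is None:
            # individual fruit: at least 24 h; packaged/bulk: 2-3 days
            object.__setattr__(
                self, "min_duration_h", 48.0 if self.protocol == "bulk" else 24.0
            )
        if self.protocol == "bulk" and self.tissue_resistance_s_cm is None:
            raise ValueError(
                "bulk protocol needs tissue_resistance_s_cm (from a prior "
                "individual-fruit measurement) to partition the resistances"
            )
        return self


def _read_csv(path, required, kind) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise ParseError(f"{path}: cannot parse {kind} CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: {kind} CSV missing columns {missing}; found {list(df.columns)}"
        )
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: unparseable ISO-8601 timestamp: {exc}") from exc
    return df


def read_weighing_csv(path) -> Dict[str, WeighingSeries]:
    """Read a weighing log into one validated series per item_id.

    Rejects duplicate (item, timestamp) pairs, non-monotone time, and
    non-positive or non-finite masses, naming the offending rows.
    """
    df = _read_csv(path, WEIGHING_COLUMNS, "weighing")
    if df["mass_g"].isna().any():
        rows = df.index[df["mass_g"].isna()].tolist()
        raise DataValidationError(f"{path}: missing mass values at rows {rows}")
    if (df["mass_g"] <= 0).any():
        rows = df.index[df["mass_g"] <= 0].tolist()
        raise DataValidationError(f"{path}: non-positive mass at rows {rows}")
    dup = df.duplicated(subset=["item_id", "timestamp"])
    if dup.any():
        raise DataValidationError(
            f"{path}: duplicate (item_id, timestamp) at rows {df.index[dup].tolist()}"
        )
    series: Dict[str, WeighingSeries] = {}
    for item_id, group in df.groupby("item_id", sort=False):
        if not group["timestamp"].is_monotonic_increasing:
            raise DataValidationError(
                f"{path}: timestamps for item {item_id!r} are not increasing"
            )
        series[str(item_id)] = WeighingSeries(
            item_id=str(item_id),
            timestamps=pd.DatetimeIndex(group["timestamp"]),
            mass_g=group["mass_g"].to_numpy(float),
        )
    return series


def write_weighing_csv(series_by_id: Dict[str, WeighingSeries], path) -> None:
    """Write series to CSV in the schema :func:`read_weighing_csv` accepts."""
    frames = [s.to_frame() for s in series_by_id.values()]
    out = pd.concat(frames, ignore_index=True)
    out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    out.to_csv(path, index=False)


def read_climate_csv(path) -> ClimateLog:
    """Read a climate log; validates monotone time and rH in [0, 100] %."""
    df = _read_csv(path, CLIMATE_COLUMNS, "climate")
    return ClimateLog(data=df)


def write_climate_csv(log: ClimateLog, path) -> None:
    out = log.data.copy()
    out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    out.to_csv(path, index=False)


def mean_climate(
    log: ClimateLog,
    t_start: pd.Timestamp,
    t_end: pd.Timestamp,
) -> Tuple[float, float, Optional[float]]:
    """Time-weighted mean (temp_c, rh_pct, pbar_pa) over [t_start, t_end].

    The log is treated as piecewise linear between samples; the mean is the
    exact trapezoidal integral over the window divided by its length, with
    the edge values obtained by interpolation. The window must lie inside
    the logged period.
    """
    t_start, t_end = pd.Timestamp(t_start), pd.Timestamp(t_end)
    if t_end < t_start:
        raise CoverageError("t_end precedes t_start")
    ts = log.timestamps
    if t_start < ts[0] or t_end > ts[-1]:
        raise CoverageError(
            f"window [{t_start}, {t_end}] extends beyond the climate log "
            f"coverage [{ts[0]}, {ts[-1]}]"
        )
    t_sec = (ts - ts[0]).total_seconds().to_numpy()
    w0 = (t_start - ts[0]).total_seconds()
    w1 = (t_end - ts[0]).total_seconds()

    columns = ["temp_c", "rh_pct"] + (["pbar_pa"] if log.has_pressure else [])
    inside = (t_sec > w0) & (t_sec < w1)
    grid = np.concatenate(([w0], t_sec[inside], [w1]))

    means = []
    for col in columns:
        values = log.data[col].to_numpy(float)
        on_grid = np.interp(grid, t_sec, values)
        if w1 == w0:
            means.append(float(on_grid[0]))
        else:
            means.append(float(np.trapezoid(on_grid, grid) / (w1 - w0)))
    temp_c, rh_pct = means[0], means[1]
    pbar = means[2] if log.has_pressure else None
    return temp_c, rh_pct, pbar
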