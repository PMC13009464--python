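"""Spatial domain grid and the semi-monthly time axis.

The pipeline operates on a regular latitude/longitude grid with per-cell
elevation and a land mask, and produces output on a semi-monthly time grid
(the 1st and 15th of every month), matching the sampling cadence of fire
agencies' fuel-moisture programs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

#: Mean length of a semi-monthly period in days, used to convert lags
#: expressed in periods into days (3.9 periods ~ 58 days).
SEMIMONTHLY_PERIOD_DAYS = 14.9


@dataclass
class DomainGrid:
    """Regular lat/lon grid with elevation (m a.m.s.l.) and a land mask.

    ``lats`` and ``lons`` are ascending 1-D coordinate vectors;
    ``elevation`` and ``land_mask`` are 2-D ``(lat, lon)`` arrays.
    """

    lats: np.ndarray
    lons: np.ndarray
    elevation: np.ndarray
    land_mask: np.ndarray

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.lats.ndim != 1 or self.lons.ndim != 1:
            raise ValueError("lats and lons must be 1-D coordinate vectors")
        if np.any(np.diff(self.lats) <= 0) or np.any(np.diff(self.lons) <= 0):
            raise ValueError("lats and lons must be strictly ascending")
        shape = (self.lats.size, self.lons.size)
        if self.elevation.shape != shape or self.land_mask.shape != shape:
            raise ValueError(f"elevation/land_mask must have shape {shape}")
        if not np.all(np.isfinite(self.elevation[self.land_mask])):
            raise ValueError("elevation must be finite on land cells")
        if not self.land_mask.any():
            raise ValueError("land mask must contain at least one land cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lats.size, self.lons.size)

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "elevation": (("lat", "lon"), self.elevation),
                "land_mask": (("lat", "lon"), self.land_mask.astype(np.int8)),
            },
            coords={"lat": self.lats, "lon": self.lons},
            attrs={"description": "model domain grid"},
        )

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "DomainGrid":
        return cls(
            lats=ds["lat"].values,
            lons=ds["lon"].values,
            elevation=ds["elevation"].values,
            land_mask=ds["land_mask"].values.astype(bool),
        )

    def cell_index(self, lat: float, lon: float) -> tuple[int, int]:
        """Index of the grid cell whose center is nearest to (lat, lon)."""
        i = int(np.argmin(np.abs(self.lats - lat)))
        j = int(np.argmin(np.abs(self.lons - lon)))
        return i, j

    def contains(self, lat: float, lon: float) -> bool:
        return bool(
            self.lats[0] <= lat <= self.lats[-1]
            and self.lons[0] <= lon <= self.lons[-1]
        )


def semimonthly_steps(start, end) -> pd.DatetimeIndex:
    """All 1st/15th-of-month time steps within [start, end] inclusive."""
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    months = pd.period_range(start.to_period("M"), end.to_period("M"), freq="M")
    steps = []
    for m in months:
        for day in (1, 15):
            ts = pd.Timestamp(year=m.year, month=m.month, day=day)
            if start <= ts <= end:
                steps.append(ts)
    return pd.DatetimeIndex(steps)


def periods_to_days(periods: float) -> float:
    """Convert a lag in semi-monthly periods to days."""
    return periods * SEMIMONTHLY_PERIOD_DAYS
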