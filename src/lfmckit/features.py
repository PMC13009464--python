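"""Derived daily variables and the lagged model predictors.

Vegetation water status responds to antecedent conditions, so the model
predictors are trailing-window aggregates of the daily forcing: 90-day
total precipitation, 90-day mean temperature, 150-day mean insolation,
30-day mean VPD and wind, 7-day mean soil moisture, 30-day total
precipitation — plus two instantaneous terms, astronomical day length and
the NIRv greenness composite. Reference evapotranspiration uses the FAO-56
daily Penman-Monteith formulation; climatic water deficit is ETo - AET.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

#: The default (final) predictor set. Window lengths in days are encoded in
#: the names; NIRv and DL are instantaneous.
DEFAULT_PREDICTORS = ["P90", "T90", "SW150", "NIRv", "DL", "SM7", "W30", "VPD30", "P30"]

#: (source daily variable, window days, aggregation) per lagged predictor.
PREDICTOR_RECIPES: dict[str, tuple[str, int, str]] = {
    "P90": ("P", 90, "total"),
    "T90": ("T", 90, "mean"),
    "SW150": ("SW", 150, "mean"),
    "SM7": ("SM", 7, "mean"),
    "W30": ("u", 30, "mean"),
    "VPD30": ("VPD", 30, "mean"),
    "P30": ("P", 30, "total"),
    # optional "initial tested" variants, not in the default set
    "T150": ("T", 150, "mean"),
    "RH150": ("RH", 150, "mean"),
    "P7": ("P", 7, "total"),
    "P3": ("P", 3, "total"),
    "ETO90": ("ETo", 90, "total"),
    "CWD90": ("CWD", 90, "total"),
    "CWD30": ("CWD", 30, "total"),
}


# ---------------------------------------------------------------------------
# scalar/array physics

def vpd(es, ea):
    """Vapor pressure deficit (kPa): saturation minus actual."""
    es = np.asarray(es, dtype=float)
    ea = np.asarray(ea, dtype=float)
    if np.any(ea > es + 1e-12):
        raise ValueError("actual vapor pressure exceeds saturation vapor pressure")
    return es - ea


def climatic_water_deficit(eto, aet):
    """CWD (mm/day) = ETo - AET; negative values are kept (wet surplus)."""
    return np.asarray(eto, dtype=float) - np.asarray(aet, dtype=float)


def day_length(lat: float, dates) -> np.ndarray:
    """Astronomical day length (hours) from the standard sunrise equation.

    Valid for |lat| < 66.5 deg (no polar day/night handling).
    """
    if abs(lat) >= 66.5:
        raise ValueError("day_length supports only |lat| < 66.5 degrees")
    doy = pd.DatetimeIndex(np.atleast_1d(np.asarray(dates, dtype="datetime64[ns]"))).dayofyear
    decl = np.deg2rad(23.45) * np.sin(2 * np.pi * (284 + doy.to_numpy(float)) / 365.0)
    cos_h = -np.tan(np.deg2rad(lat)) * np.tan(decl)
    h = np.arccos(np.clip(cos_h, -1.0, 1.0))
    out = 24.0 / np.pi * h
    return out if out.size > 1 else float(out[0])


def adjust_wind_height(u, measurement_height_m: float = 10.0):
    """Scale wind speed to the 2 m reference height via the logarithmic
    profile factor 4.87 / ln(67.8 z - 5.42)."""
    if measurement_height_m == 2.0:
        return np.asarray(u, dtype=float)
    return np.asarray(u, dtype=float) * 4.87 / np.log(67.8 * measurement_height_m - 5.42)


def penman_monteith_eto(T, u, es, ea, Rn, Psfc, wind_height_m: float = 10.0):
    """FAO-56 daily reference evapotranspiration (mm/day), clamped at 0.

    Parameters are daily means: T air temperature (degC), u wind speed
    (m/s at ``wind_height_m``), es/ea saturation/actual vapor pressure
    (kPa), Rn net radiation (W m-2, converted internally to MJ m-2 d-1),
    Psfc surface pressure (kPa). Soil heat flux is taken as zero at the
    daily scale.
    """
    T = np.asarray(T, dtype=float)
    es = np.asarray(es, dtype=float)
    ea = np.asarray(ea, dtype=float)
    Psfc = np.asarray(Psfc, dtype=float)
    if np.any(ea > es + 1e-9):
        raise ValueError("ea > es: non-physical humidity input")
    if np.any(Psfc <= 0):
        raise ValueError("surface pressure must be positive")
    u2 = adjust_wind_height(u, wind_height_m)
    rn_mj = np.asarray(Rn, dtype=float) * 0.0864  # W m-2 -> MJ m-2 day-1
    svp_slope = 4098.0 * (0.6108 * np.exp(17.27 * T / (T + 237.3))) / (T + 237.3) ** 2
    gamma = 0.000665 * Psfc
    num = 0.408 * svp_slope * rn_mj + gamma * (900.0 / (T + 273.0)) * u2 * (es - ea)
    den = svp_slope + gamma * (1.0 + 0.34 * u2)
    return np.maximum(num / den, 0.0)


# ---------------------------------------------------------------------------
# rolling windows

def rolling_feature(series: pd.Series, window: int, mode: str, target_day=None):
    """Trailing-window aggregate, inclusive of the target day.

    ``series`` must be indexed by contiguous daily dates. The window
    [target - window + 1, target] must be fully covered, otherwise the
    result is missing (NaN). With ``target_day=None`` the full rolled
    series is returned.
    """
    if mode not in ("total", "mean"):
        raise ValueError("mode must be 'total' or 'mean'")
    agg = "sum" if mode == "total" else "mean"
    rolled = getattr(series.rolling(window=window, min_periods=window), agg)()
    if target_day is None:
        return rolled
    target_day = pd.Timestamp(target_day)
    if target_day not in rolled.index or pd.isna(rolled.loc[target_day]):
        logger.warning("rolling window %dd not covered at %s", window, target_day.date())
        return np.nan
    return float(rolled.loc[target_day])


def derived_daily(met: xr.Dataset, wind_height_m: float = 10.0) -> xr.Dataset:
    """ETo, CWD, VPD and day length from the daily forcing."""
    eto = penman_monteith_eto(
        T=met["T"].values, u=met["u"].values, es=met["es"].values,
        ea=met["ea"].values, Rn=met["Rn"].values, Psfc=met["Psfc"].values,
        wind_height_m=wind_height_m,
    )
    cwd = climatic_water_deficit(eto, met["AET"].values)
    vpd_ = vpd(met["es"].values, met["ea"].values)
    dates = pd.DatetimeIndex(met["time"].values)
    dl = np.stack([day_length(float(lat), dates) for lat in met["lat"].values], axis=1)
    dl3 = np.broadcast_to(dl[:, :, None], met["T"].shape).copy()
    return xr.Dataset(
        {
            "ETo": (("time", "lat", "lon"), eto),
            "CWD": (("time", "lat", "lon"), cwd),
            "VPD": (("time", "lat", "lon"), vpd_),
            "DL": (("time", "lat", "lon"), dl3),
        },
        coords=met.coords,
    )


def predictor_fields(
    met: xr.Dataset,
    predictors: list[str] | None = None,
    wind_height_m: float = 10.0,
) -> xr.Dataset:
    """Daily gridded lag predictors (everything except NIRv).

    The first ``max(window) - 1`` days have missing values by construction;
    the first fully valid day is (window - 1) days after forcing start, so
    with the default 150-day window predictions start 150 days in.
    """
    predictors = list(DEFAULT_PREDICTORS if predictors is None else predictors)
    derived = derived_daily(met, wind_height_m)
    source = met.merge(derived)
    out = {}
    for name in predictors:
        if name == "NIRv":
            continue
        if name == "DL":
            out["DL"] = derived["DL"]
            continue
        if name == "Elevation":
            continue
        var, window, mode = PREDICTOR_RECIPES[name]
        roller = source[var].rolling(time=window, min_periods=window)
        out[name] = roller.sum() if mode == "total" else roller.mean()
    return xr.Dataset(out, coords=met.coords)


# ---------------------------------------------------------------------------
# point sampling

def sample_at_points(
    fields: xr.Dataset,
    points: pd.DataFrame,
    nirv: xr.DataArray | None = None,
) -> pd.DataFrame:
    """Predictor vectors at (lat, lon, date) points.

    Bilinear in space and linear in time; daily fields interpolate between
    days, the semi-monthly NIRv cube between its 1st/15th steps. Points
    outside the grid hull or date range raise with the offending point.
    """
    req = {"lat", "lon", "date"}
    if not req.issubset(points.columns):
        raise ValueError(f"points must have columns {sorted(req)}")
    for _, row in points.iterrows():
        if not (
            fields["lat"].values[0] <= row["lat"] <= fields["lat"].values[-1]
            and fields["lon"].values[0] <= row["lon"] <= fields["lon"].values[-1]
        ):
            raise ValueError(
                f"point ({row['lat']:.4f}, {row['lon']:.4f}) outside the grid hull"
            )
    lat = xr.DataArray(points["lat"].to_numpy(float), dims="obs")
    lon = xr.DataArray(points["lon"].to_numpy(float), dims="obs")
    time = xr.DataArray(pd.to_datetime(points["date"]).to_numpy(), dims="obs")
    sampled = fields.interp(lat=lat, lon=lon, time=time, method="linear")
    out = points.reset_index(drop=True).copy()
    for name in sampled.data_vars:
        out[name] = np.asarray(sampled[name].values, dtype=float)
    if nirv is not None:
        nv = nirv.interp(lat=lat, lon=lon, time=time, method="linear")
        out["NIRv"] = np.asarray(nv.values, dtype=float)
    return out


# ---------------------------------------------------------------------------
# normalization

@dataclass
class NormalizationStats:
    """Per-predictor mean/sd computed on training rows only."""

    mean: pd.Series
    sd: pd.Series

    def to_dict(self) -> dict:
        return {"mean": self.mean.to_dict(), "sd": self.sd.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(mean=pd.Series(d["mean"]), sd=pd.Series(d["sd"]))


def normalize(
    rows: pd.DataFrame,
    stats: NormalizationStats | None = None,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, NormalizationStats]:
    """Z-score predictor columns.

    On the training path (``stats=None``) the statistics are computed from
    ``rows`` and returned for reuse on the prediction path; a predictor
    with zero spread raises by name.
    """
    if stats is None:
        if len(rows) < 2:
            raise ValueError("need at least 2 rows to compute normalization stats")
        columns = list(columns if columns is not None else rows.columns)
        mean = rows[columns].mean()
        sd = rows[columns].std(ddof=0)
        bad = sd.index[(sd <= 0) | ~np.isfinite(sd)].tolist()
        if bad:
            raise ValueError(f"zero/invalid standard deviation for predictors: {bad}")
        stats = NormalizationStats(mean=mean, sd=sd)
    columns = list(stats.mean.index)
    out = rows.copy()
    out[columns] = (rows[columns] - stats.mean) / stats.sd
    return out, stats
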