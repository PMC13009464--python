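"""Semi-monthly NIRv compositing from irregular cloudy scene stacks.

NIRv (near-infrared reflectance of vegetation) is NDVI times NIR
reflectance; multiplying by NDVI suppresses the non-vegetated part of
mixed pixels. The compositor turns an irregular stack of cloud-screened
scenes into gap-filled values on the semi-monthly (1st/15th) grid:

1. cloud-flagged cells dropped, NIRv computed per scene;
2. a one-pass shadow filter removes points far *below* a local linear
   trend of their temporal neighbors;
3. value screening removes NIRv <= 0 (water) and > 0.5 (outliers);
4. each semi-monthly step is estimated from the points in a centered
   120-day window — quadratic fit (n >= 6), linear fit (3 <= n <= 5),
   median (1 <= n <= 2), missing (n = 0);
5. interior temporal gaps spanning < 90 days are filled linearly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from .grids import DomainGrid, semimonthly_steps

logger = logging.getLogger(__name__)

NIRV_MAX = 0.5  # values above this are screened as outliers
WINDOW_DAYS = 120  # centered estimation window, closed on both ends
GAP_FILL_MAX_DAYS = 90  # interior gaps spanning at least this stay missing


def compute_nirv(red, nir):
    """NIRv = NDVI * NIR with NDVI = (nir - red)/(nir + red).

    Reflectances must be in [0, 1]; cells with nir + red = 0 are missing.
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if np.any((red < 0) | (red > 1) | (nir < 0) | (nir > 1)):
        raise ValueError("reflectances must lie in [0, 1]")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), np.nan)
    return ndvi * nir


def screen_values(values):
    """Set NIRv <= 0 (water signal) and > 0.5 (outliers) to missing.

    The upper screen is strictly above 0.5: a value of exactly 0.5 is kept.
    """
    values = np.asarray(values, dtype=float)
    out = values.copy()
    with np.errstate(invalid="ignore"):
        out[(values <= 0) | (values > NIRV_MAX)] = np.nan
    return out


def shadow_filter(
    dates,
    values,
    k_neighbors: int = 6,
    k_sigma: float = 2.0,
    min_deviation: float = 0.01,
) -> np.ndarray:
    """One-pass cloud-shadow filter on a single cell's time series.

    Each point is compared with a robust (Theil-Sen) line through its
    ``k_neighbors`` nearest temporal neighbors (excluding itself); the
    point is removed (set NaN) if it falls below the line by more than
    k_sigma times the robust (MAD) residual spread plus ``min_deviation``
    (an absolute floor: deviations smaller than ~2% of the index's dynamic
    range are never "substantial"). The robust line matters because shadow
    contamination in the neighbors would drag an ordinary least-squares
    fit down and mask real shadows. Only downward outliers are removed —
    shadows depress NIRv, they never raise it. Series with too few valid
    points are returned unfiltered.
    """
    t = np.asarray(pd.DatetimeIndex(dates).values.astype("datetime64[D]").astype(float))
    v = np.asarray(values, dtype=float)
    out = v.copy()
    valid = np.flatnonzero(np.isfinite(v))
    if valid.size < k_neighbors + 1:
        logger.debug("shadow_filter: only %d valid points, series unfiltered", valid.size)
        return out
    tv, vv = t[valid], v[valid]
    for pos, i in enumerate(valid):
        order = np.argsort(np.abs(tv - t[i]))
        nbr = [k for k in order if k != pos][:k_neighbors]
        tn, vn = tv[nbr] - t[i], vv[nbr]
        dt = tn[None, :] - tn[:, None]
        dv = vn[None, :] - vn[:, None]
        pairs = dt != 0
        slope = float(np.median(dv[pairs] / dt[pairs])) if pairs.any() else 0.0
        intercept = float(np.median(vn - slope * tn))
        resid_n = vn - (intercept + slope * tn)
        sigma = 1.4826 * float(np.median(np.abs(resid_n - np.median(resid_n))))
        if v[i] - intercept < -(k_sigma * sigma + min_deviation):
            out[i] = np.nan
    return out


def semimonthly_estimate(dates, values, step_date, window_days: int = WINDOW_DAYS):
    """NIRv estimate at one semi-monthly step from a filtered cell series.

    Points within the centered, closed window [step - w/2, step + w/2] are
    fitted: n >= 6 quadratic, 3-5 linear, 1-2 median, 0 missing.
    """
    t = pd.DatetimeIndex(dates)
    v = np.asarray(values, dtype=float)
    step = pd.Timestamp(step_date)
    half = pd.Timedelta(days=window_days / 2)
    mask = (t >= step - half) & (t <= step + half) & np.isfinite(v)
    n = int(mask.sum())
    if n == 0:
        return np.nan
    tt = (t[mask] - step).days.to_numpy(float)
    vv = v[mask]
    if n >= 6:
        coef = np.polynomial.polynomial.polyfit(tt, vv, 2)
        return float(coef[0])  # polynomial evaluated at t=0 (the step)
    if n >= 3:
        coef = np.polynomial.polynomial.polyfit(tt, vv, 1)
        return float(coef[0])
    return float(np.median(vv))


def gap_fill_temporal(series: pd.Series, max_gap_days: int = GAP_FILL_MAX_DAYS) -> pd.Series:
    """Fill interior semi-monthly gaps spanning < max_gap_days linearly.

    A gap's span is the day distance between the bounding valid steps; a
    run of 7 missing semi-monthly steps (~105+ days) stays missing, as do
    gaps touching either series boundary.
    """
    out = series.copy()
    valid_idx = series.index[series.notna()]
    if len(valid_idx) < 2:
        return out
    interp = series.interpolate(method="time", limit_area="inside")
    for left, right in zip(valid_idx[:-1], valid_idx[1:]):
        span = (right - left).days
        inner = series.index[(series.index > left) & (series.index < right)]
        if len(inner) == 0:
            continue
        if span < max_gap_days:
            out.loc[inner] = interp.loc[inner]
    return out


def upscale(
    fine_values: np.ndarray,
    fine_lats: np.ndarray,
    fine_lons: np.ndarray,
    grid: DomainGrid,
) -> np.ndarray:
    """Missing-aware mean aggregation of a fine raster onto the domain grid.

    Each fine cell contributes to the coarse cell whose center is nearest;
    coarse cells with no finite contributor are missing.
    """
    fine_values = np.asarray(fine_values, dtype=float)
    li = np.abs(np.asarray(fine_lats)[:, None] - grid.lats[None, :]).argmin(axis=1)
    lj = np.abs(np.asarray(fine_lons)[:, None] - grid.lons[None, :]).argmin(axis=1)
    sums = np.zeros(grid.shape)
    counts = np.zeros(grid.shape)
    ii, jj = np.meshgrid(li, lj, indexing="ij")
    finite = np.isfinite(fine_values)
    np.add.at(sums, (ii[finite], jj[finite]), fine_values[finite])
    np.add.at(counts, (ii[finite], jj[finite]), 1)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def composite_stack(
    dates,
    red: np.ndarray,
    nir: np.ndarray,
    cloud: np.ndarray,
    grid: DomainGrid,
    start,
    end,
    k_neighbors: int = 6,
    k_sigma: float = 2.0,
    window_days: int = WINDOW_DAYS,
    gap_fill: bool = True,
) -> xr.DataArray:
    """Full compositing pipeline: scene stack -> semi-monthly NIRv cube.

    Sea cells are left missing. Output values obey the screen: (0, 0.5].
    """
    steps = semimonthly_steps(start, end)
    nirv_scenes = compute_nirv(red, nir)
    nirv_scenes = np.where(cloud, np.nan, nirv_scenes)
    nirv_scenes = screen_values(nirv_scenes)
    n_lat, n_lon = grid.shape
    cube = np.full((len(steps), n_lat, n_lon), np.nan)
    dates = pd.DatetimeIndex(dates)
    for i in range(n_lat):
        for j in range(n_lon):
            if not grid.land_mask[i, j]:
                continue
            series = shadow_filter(dates, nirv_scenes[:, i, j], k_neighbors, k_sigma)
            for k, step in enumerate(steps):
                cube[k, i, j] = semimonthly_estimate(dates, series, step, window_days)
    cube = screen_values(cube)  # regression extrapolation can leave the range
    da = xr.DataArray(
        cube,
        dims=("time", "lat", "lon"),
        coords={"time": steps, "lat": grid.lats, "lon": grid.lons},
        name="NIRv",
    )
    if gap_fill:
        filled = da.values.copy()
        for i in range(n_lat):
            for j in range(n_lon):
                if not grid.land_mask[i, j]:
                    continue
                s = pd.Series(da.values[:, i, j], index=steps)
                filled[:, i, j] = gap_fill_temporal(s).to_numpy()
        da = da.copy(data=filled)
    return da


def nearest_scene_baseline(dates, nirv_scenes: np.ndarray, steps) -> np.ndarray:
    """Naive baseline: the (screened) value of the temporally nearest scene
    with valid data at each cell and step. Used only as a comparison
    yardstick for compositor skill."""
    dates = pd.DatetimeIndex(dates)
    t = dates.values.astype("datetime64[D]").astype(float)
    out = np.full((len(steps), *nirv_scenes.shape[1:]), np.nan)
    for k, step in enumerate(steps):
        order = np.argsort(np.abs(t - np.datetime64(step, "D").astype(float)))
        for idx in order:
            missing = ~np.isfinite(out[k])
            if not missing.any():
                break
            out[k][missing] = nirv_scenes[idx][missing]
    return out
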