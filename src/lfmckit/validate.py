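"""Validation against point observations.

The gridded product is linearly interpolated — bilinearly in space,
linearly in time — to the time and location of every observation, and
scatter statistics are computed: MAE, RMSE, MBE (prediction minus
observation, so a negative MBE means under-prediction), R^2 and the OLS
line of predicted on observed. R^2 is reported both as squared Pearson
correlation (the scatter-plot convention, the default) and as the
coefficient of determination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    mae: float
    rmse: float
    mbe: float
    r2_pearson: float
    r2_cod: float
    slope: float
    intercept: float
    n: int
    condition: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def metrics(obs, pred, condition_max_obs: float | None = None) -> MetricsReport:
    """Scatter statistics for paired (observation, prediction) values.

    ``condition_max_obs`` restricts the pairs to observations strictly
    below the threshold (e.g. the 79% LFMC large-fire-growth threshold);
    an infinite threshold reproduces the unconditioned report.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    ok = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[ok], pred[ok]
    label = None
    if condition_max_obs is not None and np.isfinite(condition_max_obs):
        keep = obs < condition_max_obs
        obs, pred = obs[keep], pred[keep]
        label = f"obs < {condition_max_obs:g}%"
    if obs.size < 2:
        raise ValueError("metrics needs at least 2 pairs after conditioning")
    err = pred - obs
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    mbe = float(np.mean(err))
    if np.std(obs) > 0 and np.std(pred) > 0:
        r2p = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    else:
        r2p = np.nan
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2cod = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    slope, intercept = np.polyfit(obs, pred, 1) if np.std(obs) > 0 else (np.nan, np.nan)
    return MetricsReport(
        mae=mae, rmse=rmse, mbe=mbe, r2_pearson=r2p, r2_cod=r2cod,
        slope=float(slope), intercept=float(intercept), n=int(obs.size),
        condition=label,
    )


def colocate(
    cube: xr.DataArray, observations: pd.DataFrame, value_col: str = "model"
) -> pd.DataFrame:
    """Interpolate a (time, lat, lon) cube to each observation's site/date.

    Observations outside the cube's spatial hull or time span are skipped
    (counted in the log) rather than extrapolated.
    """
    obs = observations.reset_index(drop=True).copy()
    t = pd.to_datetime(obs["date"])
    inside = (
        (obs["lat"] >= float(cube["lat"].min()))
        & (obs["lat"] <= float(cube["lat"].max()))
        & (obs["lon"] >= float(cube["lon"].min()))
        & (obs["lon"] <= float(cube["lon"].max()))
        & (t >= pd.Timestamp(cube["time"].values[0]))
        & (t <= pd.Timestamp(cube["time"].values[-1]))
    )
    n_skipped = int((~inside).sum())
    if n_skipped:
        logger.info("colocate: %d observations outside the cube, skipped", n_skipped)
    kept = obs[inside]
    sampled = cube.interp(
        lat=xr.DataArray(kept["lat"].to_numpy(float), dims="obs"),
        lon=xr.DataArray(kept["lon"].to_numpy(float), dims="obs"),
        time=xr.DataArray(pd.to_datetime(kept["date"]).to_numpy(), dims="obs"),
        method="linear",
    )
    out = kept.copy()
    out[value_col] = np.asarray(sampled.values, dtype=float)
    return out
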