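"""Lag-time exploration: which antecedent window drives LFMC?

For each candidate predictor, site LFMC series and the predictor are both
resampled to semi-monthly periods and cross-correlated at lags of
0..max_lag periods; the best lag (largest |Pearson r|) is averaged across
sites. The report is advisory: the production pipeline keeps its
configured 90/150-day windows regardless (fixed windows generalized
better than the discovered lags), so nothing here feeds back into the
model automatically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import periods_to_days, semimonthly_steps

logger = logging.getLogger(__name__)

#: Variables that accumulate over a period (everything else is averaged).
SUM_VARIABLES = {"P", "ETo", "CWD"}


def resample_semimonthly(series: pd.Series, mode: str) -> pd.Series:
    """Aggregate a daily series onto the semi-monthly grid.

    Each period covers [step, next step); ``mode`` is 'sum' (precipitation,
    ETo, CWD) or 'mean' (state variables). Periods with no data are missing.
    """
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    series = series.sort_index()
    steps = semimonthly_steps(series.index.min(), series.index.max())
    if len(steps) == 0:
        return pd.Series(dtype=float)
    edges = steps.append(pd.DatetimeIndex([series.index.max() + pd.Timedelta(days=1)]))
    out = np.full(len(steps), np.nan)
    for k in range(len(steps)):
        chunk = series[(series.index >= edges[k]) & (series.index < edges[k + 1])].dropna()
        if len(chunk):
            out[k] = chunk.sum() if mode == "sum" else chunk.mean()
    return pd.Series(out, index=steps)


def default_mode(variable: str) -> str:
    return "sum" if variable in SUM_VARIABLES else "mean"


def best_lag(
    lfmc: pd.Series, predictor: pd.Series, max_lag: int = 12, min_overlap: int = 20
) -> tuple[float, float]:
    """Best lag (periods) of a predictor against LFMC by |Pearson r|.

    Correlates LFMC(t) with predictor(t - lag) for lag = 0..max_lag on the
    shared semi-monthly index; ties break toward the smaller lag. Returns
    (nan, nan) when fewer than ``min_overlap`` pairs remain.
    """
    joined = pd.concat({"lfmc": lfmc, "pred": predictor}, axis=1)
    best = (np.nan, np.nan)
    best_abs = -np.inf
    for lag in range(max_lag + 1):
        pairs = pd.concat(
            {"lfmc": joined["lfmc"], "pred": joined["pred"].shift(lag)}, axis=1
        ).dropna()
        if len(pairs) < min_overlap:
            continue
        if pairs["lfmc"].std() == 0 or pairs["pred"].std() == 0:
            continue
        r = float(pairs["lfmc"].corr(pairs["pred"]))
        if abs(r) > best_abs + 1e-15:  # strict: ties keep the smaller lag
            best_abs = abs(r)
            best = (float(lag), r)
    if not np.isfinite(best_abs):
        logger.warning("best_lag: insufficient overlap (<%d pairs)", min_overlap)
    return best


@dataclass
class LagReport:
    """Per-predictor site-averaged best lags, in periods and days."""

    table: pd.DataFrame  # columns: predictor, mean_lag_periods, mean_lag_days, mean_abs_r, n_sites

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def aggregate_lags(per_site: dict[str, list[tuple[float, float]]]) -> LagReport:
    """Average per-site best lags across sites for each predictor.

    ``per_site`` maps predictor name -> list of (lag_periods, r) per site;
    missing site entries (nan lag) are ignored. Days use the mean
    semi-monthly period length (3.9 periods ~ 58 days).
    """
    rows = []
    for name, entries in per_site.items():
        lags = np.array([e[0] for e in entries], dtype=float)
        rs = np.array([e[1] for e in entries], dtype=float)
        ok = np.isfinite(lags)
        if not ok.any():
            rows.append(
                {"predictor": name, "mean_lag_periods": np.nan, "mean_lag_days": np.nan,
                 "mean_abs_r": np.nan, "n_sites": 0}
            )
            continue
        mean_lag = float(lags[ok].mean())
        rows.append(
            {
                "predictor": name,
                "mean_lag_periods": mean_lag,
                "mean_lag_days": periods_to_days(mean_lag),
                "mean_abs_r": float(np.abs(rs[ok]).mean()),
                "n_sites": int(ok.sum()),
            }
        )
    if not any(r["n_sites"] for r in rows):
        raise ValueError("no predictor has a valid lag at any site")
    return LagReport(table=pd.DataFrame(rows))
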