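"""Per-fuel random-forest LFMC models with ensemble-spread uncertainty.

Each fuel type gets its own forest, trained on z-scored predictor vectors
at the observation points. Uncertainty follows the quantile-regression-
forest idea of reading the ensemble spread as epistemic uncertainty: the
per-prediction sigma is the standard deviation across individual tree
predictions and the 95% prediction interval is mean +/- 1.96 sigma.

Hyperparameters come from a randomized search over a parameter grid scored
by k-fold test R^2; site-wise cross-validation (each site withheld in
turn) probes spatial transferability. Normalization statistics are
recomputed from each training fold only, so no information leaks from the
held-out fold.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import LinearNDInterpolator
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, ParameterSampler

from .features import NormalizationStats, normalize, DEFAULT_PREDICTORS
from .grids import DomainGrid
from .validate import MetricsReport, metrics

logger = logging.getLogger(__name__)

Z95 = 1.96  # normal 95% interval half-width in sigmas


@dataclass
class Hyperparams:
    """Random-forest hyperparameters.

    ``max_features`` is an absolute count of predictors tried per split.
    """

    n_trees: int = 1000
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    max_depth: int = 20
    max_features: int = 3
    bootstrap: bool = True

    def sklearn_kwargs(self) -> dict:
        return dict(
            n_estimators=self.n_trees,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            max_depth=self.max_depth,
            max_features=self.max_features,
            bootstrap=self.bootstrap,
        )


#: Tuned defaults per fuel type. The black sage depth is read as 110 from a
#: run-together table; every entry is config-overridable.
DEFAULT_HYPERPARAMS: dict[str, Hyperparams] = {
    "chamise": Hyperparams(800, 2, 2, 50, 3, False),
    "old growth chamise": Hyperparams(1000, 2, 1, 20, 3, True),
    "black sage": Hyperparams(1000, 2, 1, 110, 3, True),
    "bigpod ceanothus": Hyperparams(1000, 2, 1, 20, 3, True),
}

#: Default randomized-search grid.
DEFAULT_TUNE_GRID = {
    "n_trees": [200, 400, 800, 1000],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 4],
    "max_depth": [20, 50, 110, None],
    "max_features": [2, 3, 5],
    "bootstrap": [True, False],
}


@dataclass
class ForestModel:
    """A fitted per-fuel forest plus everything needed to apply it."""

    estimator: RandomForestRegressor
    hyperparams: Hyperparams
    stats: NormalizationStats
    predictors: list[str]
    fuel_type: str
    seed: int
    training_range: tuple[float, float]
    fingerprint: str

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        X = self._design(rows)
        return self.estimator.predict(X)

    def predict_with_sigma(self, rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Mean-of-trees prediction and per-row tree-spread sigma."""
        X = self._design(rows)
        per_tree = np.stack([t.predict(X) for t in self.estimator.estimators_])
        return per_tree.mean(axis=0), per_tree.std(axis=0, ddof=0)

    def _design(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [p for p in self.predictors if p not in rows.columns]
        if missing:
            raise ValueError(f"rows are missing predictor columns: {missing}")
        normed, _ = normalize(rows[self.predictors], self.stats)
        X = normed[self.predictors].to_numpy(float)
        if not np.all(np.isfinite(X)):
            bad = np.flatnonzero(~np.isfinite(X).all(axis=1))
            raise ValueError(f"non-finite predictors in rows {bad[:10].tolist()}")
        return X

    def importances(self) -> pd.Series:
        return pd.Series(self.estimator.feature_importances_, index=self.predictors)


@dataclass
class CVReport:
    """Cross-validation results: per-fold metrics plus pooled held-out metrics."""

    mode: str
    folds: pd.DataFrame
    pooled: MetricsReport

    def to_frame(self) -> pd.DataFrame:
        pooled = pd.DataFrame([{"fold": "pooled", **asdict(self.pooled)}])
        return pd.concat([self.folds, pooled], ignore_index=True)


def _check_rows(rows: pd.DataFrame, predictors: list[str]) -> None:
    X = rows[predictors].to_numpy(float)
    if not np.all(np.isfinite(X)):
        bad = rows.index[~np.isfinite(X).all(axis=1)]
        raise ValueError(f"non-finite predictor values in rows {list(bad[:10])}")


def fit(
    rows: pd.DataFrame,
    hp: Hyperparams,
    seed: int,
    predictors: list[str] | None = None,
    fuel_type: str = "chamise",
    target: str = "lfmc_percent",
) -> ForestModel:
    """Fit a forest on observation rows; normalization stats ride along."""
    predictors = list(DEFAULT_PREDICTORS if predictors is None else predictors)
    _check_rows(rows, predictors)
    normed, stats = normalize(rows, columns=predictors)
    est = RandomForestRegressor(random_state=seed, n_jobs=1, **hp.sklearn_kwargs())
    y = rows[target].to_numpy(float)
    est.fit(normed[predictors].to_numpy(float), y)
    fingerprint = hashlib.sha256(
        pd.util.hash_pandas_object(rows[predictors + [target]], index=False).values.tobytes()
    ).hexdigest()[:16]
    return ForestModel(
        estimator=est,
        hyperparams=hp,
        stats=stats,
        predictors=predictors,
        fuel_type=fuel_type,
        seed=seed,
        training_range=(float(y.min()), float(y.max())),
        fingerprint=fingerprint,
    )


def tune(
    rows: pd.DataFrame,
    grid: dict | None = None,
    n_iter: int = 100,
    k: int = 5,
    seed: int = 0,
    predictors: list[str] | None = None,
    target: str = "lfmc_percent",
) -> tuple[Hyperparams, pd.DataFrame]:
    """Randomized hyperparameter search scored by mean k-fold test R^2.

    Samples ``n_iter`` combinations (without replacement when the grid is
    small enough), scores each by k-fold cross-validation, and returns the
    best-scoring combination along with the full scored table. Both the
    best and worst combinations are logged.
    """
    grid = dict(DEFAULT_TUNE_GRID if grid is None else grid)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("hyperparameter grid is empty")
    predictors = list(DEFAULT_PREDICTORS if predictors is None else predictors)
    if len(rows) < 10 * k:
        raise ValueError(f"tuning needs at least {10 * k} rows")
    n_total = int(np.prod([len(v) for v in grid.values()]))
    sampler = ParameterSampler(grid, n_iter=min(n_iter, n_total), random_state=seed)
    records = []
    for combo in sampler:
        hp = Hyperparams(
            n_trees=combo["n_trees"],
            min_samples_split=combo["min_samples_split"],
            min_samples_leaf=combo["min_samples_leaf"],
            max_depth=combo["max_depth"] if combo["max_depth"] is not None else 1_000_000,
            max_features=min(combo["max_features"], len(predictors)),
            bootstrap=combo["bootstrap"],
        )
        report = cross_validate(
            rows, hp, mode="pooled", seed=seed, k=k, predictors=predictors, target=target
        )
        records.append({**combo, "cv_r2": report.folds["r2_pearson"].mean()})
    scored = pd.DataFrame(records).sort_values("cv_r2", ascending=False).reset_index(drop=True)
    best = scored.iloc[0]
    logger.info(
        "tune: best CV R^2 %.3f, worst %.3f over %d combos",
        best["cv_r2"], scored["cv_r2"].iloc[-1], len(scored),
    )
    hp = Hyperparams(
        n_trees=int(best["n_trees"]),
        min_samples_split=int(best["min_samples_split"]),
        min_samples_leaf=int(best["min_samples_leaf"]),
        max_depth=int(best["max_depth"]) if pd.notna(best["max_depth"]) else 1_000_000,
        max_features=min(int(best["max_features"]), len(predictors)),
        bootstrap=bool(best["bootstrap"]),
    )
    return hp, scored


def cross_validate(
    rows: pd.DataFrame,
    hp: Hyperparams,
    mode: str = "pooled",
    seed: int = 0,
    k: int = 5,
    predictors: list[str] | None = None,
    target: str = "lfmc_percent",
) -> CVReport:
    """K-fold ('pooled') or leave-one-site-out ('by_site') cross-validation.

    Normalization statistics are recomputed from each training fold. Pooled
    metrics are computed over the concatenated held-out predictions.
    """
    predictors = list(DEFAULT_PREDICTORS if predictors is None else predictors)
    _check_rows(rows, predictors)
    rows = rows.reset_index(drop=True)
    if mode == "pooled":
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(f"fold{i}", tr, te) for i, (tr, te) in enumerate(splitter.split(rows))]
    elif mode == "by_site":
        sites = rows["site_id"].unique()
        if len(sites) < 2:
            raise ValueError("by_site cross-validation needs at least 2 sites")
        folds = []
        for s in sites:
            te = np.flatnonzero((rows["site_id"] == s).to_numpy())
            tr = np.flatnonzero((rows["site_id"] != s).to_numpy())
            folds.append((str(s), tr, te))
    else:
        raise ValueError("mode must be 'pooled' or 'by_site'")

    fold_rows = []
    pooled_obs, pooled_pred = [], []
    for name, tr, te in folds:
        model = fit(rows.iloc[tr], hp, seed=seed, predictors=predictors, target=target)
        pred = model.predict(rows.iloc[te])
        obs = rows.iloc[te][target].to_numpy(float)
        m = metrics(obs, pred)
        fold_rows.append({"fold": name, "n": m.n, **{f: getattr(m, f) for f in
                          ("mae", "rmse", "mbe", "r2_pearson", "r2_cod", "slope", "intercept")}})
        pooled_obs.append(obs)
        pooled_pred.append(pred)
    pooled = metrics(np.concatenate(pooled_obs), np.concatenate(pooled_pred))
    return CVReport(mode=mode, folds=pd.DataFrame(fold_rows), pooled=pooled)


def predict_grid(
    model: ForestModel,
    fields: xr.Dataset,
    nirv: xr.DataArray,
    grid: DomainGrid,
    steps,
    gap_fill: bool = True,
) -> xr.Dataset:
    """Semi-monthly gridded LFMC with per-cell sigma and 95% PI.

    Every land cell with all predictors available gets a mean-of-trees
    prediction; cells missing NIRv are gap-filled spatially afterwards
    (triangulated linear interpolation, per step). Sea cells stay missing.
    """
    steps = pd.DatetimeIndex(steps)
    missing_layers = [p for p in model.predictors
                      if p != "NIRv" and p not in fields.data_vars]
    if missing_layers:
        raise ValueError(f"missing predictor layers: {missing_layers}")
    n_lat, n_lon = grid.shape
    lfmc = np.full((len(steps), n_lat, n_lon), np.nan)
    sigma = np.full_like(lfmc, np.nan)
    land_i, land_j = np.nonzero(grid.land_mask)
    daily = fields.sel(time=steps)
    nirv_steps = nirv.sel(time=steps)
    # one flat design matrix over (step, land cell) so the per-tree pass
    # runs once instead of once per step
    cols = {}
    for p in model.predictors:
        src = nirv_steps.values if p == "NIRv" else daily[p].values
        cols[p] = src[:, land_i, land_j].ravel()
    mat = pd.DataFrame(cols)
    ok = np.isfinite(mat.to_numpy(float)).all(axis=1)
    if ok.any():
        mean = np.full(len(mat), np.nan)
        sd = np.full(len(mat), np.nan)
        mean[ok], sd[ok] = model.predict_with_sigma(mat[ok])
        kk = np.repeat(np.arange(len(steps)), land_i.size)
        ii = np.tile(land_i, len(steps))
        jj = np.tile(land_j, len(steps))
        lfmc[kk, ii, jj] = mean
        sigma[kk, ii, jj] = sd
    if gap_fill:
        for k in range(len(steps)):
            lfmc[k] = fill_spatial_gaps(lfmc[k], grid.land_mask)
            sigma[k] = fill_spatial_gaps(sigma[k], grid.land_mask)
    coords = {"time": steps, "lat": grid.lats, "lon": grid.lons}
    ds = xr.Dataset(
        {
            "lfmc": (("time", "lat", "lon"), lfmc),
            "sigma": (("time", "lat", "lon"), sigma),
            "pi_low": (("time", "lat", "lon"), lfmc - Z95 * sigma),
            "pi_high": (("time", "lat", "lon"), lfmc + Z95 * sigma),
        },
        coords=coords,
        attrs={"fuel_type": model.fuel_type},
    )
    return ds


def fill_spatial_gaps(layer: np.ndarray, land_mask: np.ndarray) -> np.ndarray:
    """Fill missing land cells by triangulated linear interpolation from
    surrounding valid land cells; sea cells are untouched and gaps outside
    the convex hull of valid cells stay missing (logged)."""
    out = layer.copy()
    holes = land_mask & ~np.isfinite(layer)
    valid = land_mask & np.isfinite(layer)
    if not holes.any():
        return out
    if valid.sum() < 3:
        logger.warning("fill_spatial_gaps: <3 valid cells, gaps left missing")
        return out
    vi, vj = np.nonzero(valid)
    hi, hj = np.nonzero(holes)
    interp = LinearNDInterpolator(np.column_stack([vi, vj]), layer[valid])
    filled = interp(np.column_stack([hi, hj]))
    out[hi, hj] = filled
    n_left = int(np.sum(~np.isfinite(out[hi, hj])))
    if n_left:
        logger.info("fill_spatial_gaps: %d boundary gap cells left missing", n_left)
    return out


def interval_coverage(
    model: ForestModel, rows: pd.DataFrame, target: str = "lfmc_percent",
    width_factor: float = 1.0,
) -> float:
    """Fraction of held-out observations inside mean +/- 1.96 sigma
    (optionally widened by ``width_factor``)."""
    mean, sd = model.predict_with_sigma(rows)
    obs = rows[target].to_numpy(float)
    half = width_factor * Z95 * sd
    inside = (obs >= mean - half) & (obs <= mean + half)
    return float(inside.mean())


# ---------------------------------------------------------------------------
# model bundle serialization

def save_model(model: ForestModel, path) -> None:
    """Model bundle: a joblib archive plus a JSON sidecar with the
    hyperparameters, normalization stats and fingerprint."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.estimator, path)
    sidecar = {
        "format_version": 1,
        "fuel_type": model.fuel_type,
        "hyperparams": asdict(model.hyperparams),
        "normalization": model.stats.to_dict(),
        "predictors": model.predictors,
        "seed": model.seed,
        "training_range": list(model.training_range),
        "fingerprint": model.fingerprint,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> ForestModel:
    path = Path(path)
    est = joblib.load(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return ForestModel(
        estimator=est,
        hyperparams=Hyperparams(**sidecar["hyperparams"]),
        stats=NormalizationStats.from_dict(sidecar["normalization"]),
        predictors=sidecar["predictors"],
        fuel_type=sidecar["fuel_type"],
        seed=sidecar["seed"],
        training_range=tuple(sidecar["training_range"]),
        fingerprint=sidecar["fingerprint"],
    )
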