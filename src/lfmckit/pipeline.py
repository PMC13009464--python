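"""End-to-end orchestration: synthetic inputs through the final NetCDF cube.

A run executes simulate -> QC -> features/NIRv -> forest (optional tune,
cross-validate, fit, grid prediction, spatial gap fill) -> quantile-mapping
bias correction (for the bias-corrected fuel) -> validation, and writes one
NetCDF product with per-fuel LFMC, ensemble sigma and 95% PI layers, plus
CSV/JSON reports and the resolved configuration for replay.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import forest, nirv, obs_qc, qmcorrect, synthetic, validate
from .features import predictor_fields, sample_at_points, DEFAULT_PREDICTORS
from .grids import DomainGrid, semimonthly_steps

logger = logging.getLogger(__name__)

#: Longest lag window: predictions begin this many days after forcing start.
SPINUP_DAYS = 150

#: Threshold below which large fire growth becomes more likely in chamise;
#: validation reports conditional metrics under it.
FIRE_DANGER_LFMC = 79.0


def _strict(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclass
class FuelConfig:
    n_sites: int = 12
    dropout: float = 0.15
    bias_correct: bool = False
    constant_bias_range: float = 0.0   # site biases ~ U(-range, range)
    tail_bias_amplitude: float = 0.0   # quantile-dependent extra bias
    hyperparams: dict | None = None

    @classmethod
    def from_dict(cls, d: dict, name: str) -> "FuelConfig":
        _strict(d, set(cls.__dataclass_fields__), f"fuels.{name}")
        return cls(**d)


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run (strict schema)."""

    n_lat: int = 12
    n_lon: int = 12
    start: str = "1998-01-01"
    end: str = "2007-12-31"
    seed: int = 0
    predictors: list = field(default_factory=lambda: list(DEFAULT_PREDICTORS))
    fuels: dict = field(
        default_factory=lambda: {
            "chamise": FuelConfig(
                n_sites=12, bias_correct=True,
                constant_bias_range=15.0, tail_bias_amplitude=8.0,
            ),
            "black sage": FuelConfig(n_sites=4),
        }
    )
    noise_sd: float = 10.0
    revisit_days: int = 12
    cloud_fraction: float = 0.3
    shadow_k_neighbors: int = 6
    shadow_k_sigma: float = 2.0
    qm_candidates: list = field(default_factory=lambda: list(qmcorrect.DEFAULT_Q_CANDIDATES))
    qm_choose_q: bool = False
    qm_num_quantiles: int = 30
    qm_smoothing: float = 0.01
    cv_modes: list = field(default_factory=lambda: ["pooled", "by_site"])
    tune_enabled: bool = False
    tune_n_iter: int = 100
    site_exclusions: list = field(default_factory=list)
    min_site_obs: int = 25
    min_fuel_obs: int = 500

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        _strict(d, set(cls.__dataclass_fields__), "config")
        fuels = d.pop("fuels", None)
        cfg = cls(**d)
        if fuels is not None:
            cfg.fuels = {
                name: fc if isinstance(fc, FuelConfig) else FuelConfig.from_dict(fc or {}, name)
                for name, fc in fuels.items()
            }
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fuels"] = {k: asdict(v) if isinstance(v, FuelConfig) else v for k, v in self.fuels.items()}
        return d


def demo_config(seed: int = 0) -> PipelineConfig:
    """The default desk-scale demonstration run: 10 years, 12x12 grid,
    12 chamise sites with planted biases plus a sparser second fuel."""
    return PipelineConfig(seed=seed)


# ---------------------------------------------------------------------------
# cube I/O

def write_cube(cube: xr.Dataset, path) -> None:
    """Write the product cube as NetCDF (dims time, lat, lon)."""
    for var in cube.data_vars:
        if tuple(cube[var].dims) != ("time", "lat", "lon"):
            raise ValueError(f"variable {var} does not have dims (time, lat, lon)")
    enc = {v: {"_FillValue": np.nan} for v in cube.data_vars}
    cube["lat"].attrs.setdefault("units", "degrees_north")
    cube["lon"].attrs.setdefault("units", "degrees_east")
    cube.to_netcdf(path, engine="scipy", encoding=enc)


def read_cube(path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()


# ---------------------------------------------------------------------------
# run

def _truth_for_fuel(fc: FuelConfig, sites, noise_sd: float, seed: int) -> synthetic.SyntheticTruth:
    rng = np.random.default_rng(seed)
    bias: dict = {}
    for s in sites:
        b = float(rng.uniform(-fc.constant_bias_range, fc.constant_bias_range))
        if fc.tail_bias_amplitude > 0:
            amp = fc.tail_bias_amplitude
            tail = synthetic.tail_heavy_bias(float(rng.uniform(0.5 * amp, amp)))
            bias[s.site_id] = (lambda b0, t: (lambda q: b0 + t(q)))(b, tail)
        else:
            bias[s.site_id] = b
    return synthetic.SyntheticTruth(site_bias=bias, noise_sd=noise_sd, seed=seed)


def run_all(config: PipelineConfig, outdir, write_scenes: bool = False) -> dict:
    """Execute the full pipeline; returns a manifest of outputs and reports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    start, end = pd.Timestamp(config.start), pd.Timestamp(config.end)
    pred_start = start + pd.Timedelta(days=SPINUP_DAYS)
    steps = semimonthly_steps(pred_start, end)

    logger.info("stage simulate: domain %dx%d, %s..%s, seed %d",
                config.n_lat, config.n_lon, start.date(), end.date(), seed)
    grid = synthetic.generate_domain(config.n_lat, config.n_lon, seed)
    met = synthetic.generate_forcing(grid, start, end, seed + 1)
    scenes = synthetic.generate_scenes(
        grid, start, end, config.revisit_days, config.cloud_fraction, seed + 2
    )

    logger.info("stage features: predictors %s", config.predictors)
    fields = predictor_fields(met, config.predictors)

    logger.info("stage nirv: compositing %d scenes", len(scenes.dates))
    nirv_cube = nirv.composite_stack(
        scenes.dates, scenes.red, scenes.nir, scenes.cloud, grid, pred_start, end,
        k_neighbors=config.shadow_k_neighbors, k_sigma=config.shadow_k_sigma,
    )

    # --- synthetic observations per fuel
    all_obs = []
    fuel_sites: dict[str, list] = {}
    for n_fuel, (fuel, fc) in enumerate(config.fuels.items()):
        sites = synthetic.make_sites(
            grid, fc.n_sites, seed + 10 + n_fuel, prefix=f"{fuel.replace(' ', '_')}_"
        )
        fuel_sites[fuel] = sites
        schedule = synthetic.observation_schedule(
            pred_start, end, sites, fc.dropout, seed + 20 + n_fuel
        )
        coords = {s.site_id: s for s in sites}
        schedule["lat"] = [coords[s].lat for s in schedule["site_id"]]
        schedule["lon"] = [coords[s].lon for s in schedule["site_id"]]
        rows = sample_at_points(fields, schedule, nirv_cube)
        rows = rows.dropna(subset=[p for p in config.predictors])
        truth = _truth_for_fuel(fc, sites, config.noise_sd, seed + 30 + n_fuel)
        obs = synthetic.sample_observations(
            truth, rows, sites, fuel_type=fuel, grid=grid, seed=seed + 40 + n_fuel
        )
        all_obs.append(obs)
    obs_raw = pd.concat(all_obs, ignore_index=True)
    obs_path = outdir / "observations_raw.csv"
    obs_qc.write_observations(obs_raw.drop(columns=["lfmc_true"]), obs_path)

    logger.info("stage qc: %d raw records", len(obs_raw))
    obs_clean = obs_qc.qc_chain(
        obs_raw.drop(columns=["lfmc_true"]),
        site_exclusions=config.site_exclusions,
        min_site_obs=config.min_site_obs,
        min_fuel_obs=config.min_fuel_obs,
    )
    obs_qc.write_observations(obs_clean, outdir / "observations_qc.csv")
    obs_qc.qc_report(obs_clean).to_csv(outdir / "qc_report.csv", index=False)

    cube_vars = {}
    reports: dict = {"fuels": {}, "seed": seed}
    for fuel, fc in config.fuels.items():
        fuel_obs = obs_clean[obs_clean["fuel_type"] == fuel]
        if fuel_obs.empty:
            logger.warning("fuel %s removed entirely by QC, skipped", fuel)
            continue
        design = sample_at_points(fields, fuel_obs, nirv_cube).dropna(
            subset=list(config.predictors)
        )
        hp = (
            forest.Hyperparams(**fc.hyperparams)
            if fc.hyperparams
            else forest.DEFAULT_HYPERPARAMS.get(fuel, forest.Hyperparams())
        )
        if config.tune_enabled:
            logger.info("stage tune: %s (%d iterations)", fuel, config.tune_n_iter)
            hp, scored = forest.tune(
                design, n_iter=config.tune_n_iter, seed=seed + 50,
                predictors=config.predictors,
            )
            scored.to_csv(outdir / f"tune_{fuel.replace(' ', '_')}.csv", index=False)
        cv_reports = {}
        for mode in config.cv_modes:
            rep = forest.cross_validate(
                design, hp, mode=mode, seed=seed + 60, predictors=config.predictors
            )
            rep.to_frame().to_csv(
                outdir / f"cv_{mode}_{fuel.replace(' ', '_')}.csv", index=False
            )
            cv_reports[mode] = rep.pooled.to_dict()
        model = forest.fit(design, hp, seed=seed + 70, predictors=config.predictors,
                           fuel_type=fuel)
        forest.save_model(model, outdir / f"model_{fuel.replace(' ', '_')}.joblib")
        cube = forest.predict_grid(model, fields, nirv_cube, grid, steps)
        key = fuel.replace(" ", "_")
        cube_vars[f"lfmc_{key}"] = cube["lfmc"]
        cube_vars[f"lfmc_{key}_sigma"] = cube["sigma"]
        cube_vars[f"lfmc_{key}_pi_low"] = cube["pi_low"]
        cube_vars[f"lfmc_{key}_pi_high"] = cube["pi_high"]
        reports["fuels"][fuel] = {
            "n_training_rows": int(len(design)),
            "hyperparams": asdict(hp),
            "cv": cv_reports,
            "importances": model.importances().to_dict(),
        }

        co = validate.colocate(cube["lfmc"], fuel_obs)
        m_all = validate.metrics(co["lfmc_percent"], co["model"])
        m_low = None
        if (co["lfmc_percent"] < FIRE_DANGER_LFMC).sum() >= 2:
            m_low = validate.metrics(
                co["lfmc_percent"], co["model"], condition_max_obs=FIRE_DANGER_LFMC
            )
        reports["fuels"][fuel]["validation_raw"] = m_all.to_dict()
        reports["fuels"][fuel]["validation_raw_low"] = m_low.to_dict() if m_low else None

        if fc.bias_correct:
            logger.info("stage biascorrect: %s", fuel)
            bc = bias_correct_fuel(
                cube["lfmc"], fuel_obs, fuel_sites[fuel], grid, steps, config, reports["fuels"][fuel]
            )
            if bc is not None:
                corrected, corr_field = bc
                cube_vars[f"lfmc_{key}_bc"] = corrected
                cube_vars[f"lfmc_{key}_correction"] = corr_field
                cob = validate.colocate(corrected, fuel_obs)
                reports["fuels"][fuel]["validation_bc"] = validate.metrics(
                    cob["lfmc_percent"], cob["model"]
                ).to_dict()
                if (cob["lfmc_percent"] < FIRE_DANGER_LFMC).sum() >= 2:
                    reports["fuels"][fuel]["validation_bc_low"] = validate.metrics(
                        cob["lfmc_percent"], cob["model"],
                        condition_max_obs=FIRE_DANGER_LFMC,
                    ).to_dict()

    product = xr.Dataset(cube_vars)
    product["elevation"] = (("lat", "lon"), grid.elevation)
    product["land_mask"] = (("lat", "lon"), grid.land_mask.astype(np.int8))
    # NetCDF writer requires uniform dims; store grid layers separately
    grid_ds = product[["elevation", "land_mask"]]
    product = product.drop_vars(["elevation", "land_mask"])
    cube_path = outdir / "lfmc_cube.nc"
    write_cube(product, cube_path)
    grid_ds.to_netcdf(outdir / "domain_grid.nc", engine="scipy")
    synthetic.write_forcing(met, outdir / "forcing.nc")
    if write_scenes:
        synthetic.write_scenes(scenes, outdir / "scenes")

    (outdir / "reports.json").write_text(json.dumps(reports, indent=2, default=float))
    (outdir / "config_resolved.yaml").write_text(yaml.safe_dump(config.to_dict()))
    manifest = {
        "cube": str(cube_path),
        "reports": str(outdir / "reports.json"),
        "config": str(outdir / "config_resolved.yaml"),
        "observations": str(obs_path),
        "n_steps": len(steps),
        "seed": seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"manifest": manifest, "reports": reports, "cube": product, "grid": grid}


def bias_correct_fuel(
    raw: xr.DataArray,
    fuel_obs: pd.DataFrame,
    sites,
    grid: DomainGrid,
    steps: pd.DatetimeIndex,
    config: PipelineConfig,
    report: dict,
):
    """Quantile-mapping correction of one fuel's cube against its sites."""
    site_pairs = {}
    coords = {}
    for s in sites:
        so = fuel_obs[fuel_obs["site_id"] == s.site_id]
        aligned = qmcorrect.align_obs_semimonthly(so, steps)
        if aligned is None:
            continue
        ci, cj = grid.cell_index(s.lat, s.lon)
        model_series = pd.Series(raw.values[:, ci, cj], index=steps)
        site_pairs[s.site_id] = (aligned, model_series)
        coords[s.site_id] = (s.lat, s.lon, s.elev)
    if len(site_pairs) < 2:
        logger.warning("bias correction skipped: <2 usable sites")
        return None
    if config.qm_choose_q:
        Q, scan = qmcorrect.choose_num_quantiles(site_pairs, config.qm_candidates)
        report["qm_scan"] = scan.to_dict(orient="records")
    else:
        Q = config.qm_num_quantiles
    report["qm_num_quantiles"] = Q
    tables = {}
    for sid, (obs_s, model_s) in site_pairs.items():
        t = qmcorrect.site_quantile_corrections(obs_s, model_s, Q)
        if t is not None:
            tables[sid] = t
    corr = qmcorrect.correction_fields(raw, tables, coords, grid, config.qm_smoothing)
    corrected = qmcorrect.bias_correct_cube(raw, corr)
    return corrected, corr
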