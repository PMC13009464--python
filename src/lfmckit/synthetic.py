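"""Seeded synthetic domains, forcing, satellite scenes, and observations.

Every downstream stage of the pipeline (QC, feature engineering, NIRv
compositing, forest training, bias correction, validation) is exercised on
data from this module, so its outputs carry known ground truth: a planted
LFMC-generating function of the predictors, truth flags for cloud shadows,
and known per-site observation biases.

The generator emulates the statistical structure the pipeline needs from a
Mediterranean-climate domain — winter-concentrated stochastic storms, a
sinusoidal annual temperature cycle with an elevation lapse, humidity
anti-correlated with temperature, a leaky-bucket soil moisture recursion,
and a smooth seasonal greenness signal observed through irregular, cloudy
satellite revisits. It does not attempt meteorological realism beyond that
(no orographic precipitation, no wind events).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .features import penman_monteith_eto
from .grids import DomainGrid, semimonthly_steps
from .obs_qc import SiteMeta

MET_VARS = ["P", "T", "RH", "SW", "SM", "AET", "Psfc", "Rn", "es", "ea", "u"]

#: LFMC physical plausibility range (%): ~30% is effectively dead fuel,
#: >300% occurs only in the wettest tissue.
LFMC_CLIP = (30.0, 300.0)


@dataclass
class SceneStack:
    """A stack of irregular optical scenes over the domain.

    ``red``/``nir`` are top-of-canopy reflectances in [0, 1] with shape
    ``(n_scenes, n_lat, n_lon)``. ``cloud`` marks cells the (emulated)
    provider cloud filter would flag; ``shadow`` is the generator's truth
    flag for cloud-shadow contamination (for test oracles only, a real
    stack has no such flag). ``truth_nirv`` is the clean seasonal NIRv each
    scene would have shown without clouds, shadows or sensor noise.
    """

    dates: pd.DatetimeIndex
    red: np.ndarray
    nir: np.ndarray
    cloud: np.ndarray
    shadow: np.ndarray
    truth_nirv: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.dates.values.astype("datetime64[D]").astype(int)) <= 0):
            raise ValueError("scene dates must be strictly increasing")


@dataclass
class SyntheticTruth:
    """The planted LFMC-generating function and observation error model.

    ``g`` maps predictor vectors to true LFMC as a smooth monotone blend:
    increasing and saturating in 90-day precipitation, linear in 7-day soil
    moisture, NIRv and day length, decreasing in 30-day VPD — nonlinear
    enough that a forest must actually learn it, monotone enough to reason
    about. ``site_bias`` maps a site id to either a constant additive bias
    (%) or a callable of the true-LFMC quantile (tail-heavy biases emulate
    systematic sampling error in the peak wet and dry seasons).
    """

    coefficients: dict = field(
        default_factory=lambda: {
            "intercept": 40.0,
            "p90": 120.0,
            "p90_half_sat": 150.0,  # mm at which the precip response is half saturated
            "sm7": 150.0,
            "nirv": 100.0,
            "vpd30": 15.0,
            "dl": 2.0,
        }
    )
    site_bias: dict = field(default_factory=dict)
    noise_sd: float = 10.0
    seed: int = 0

    def g(self, predictors: pd.DataFrame) -> np.ndarray:
        """True LFMC (%) for rows of predictors, clipped to [30, 300]."""
        c = self.coefficients
        p90 = predictors["P90"].to_numpy(float)
        sat = p90 / (p90 + c["p90_half_sat"])
        lfmc = (
            c["intercept"]
            + c["p90"] * sat
            + c["sm7"] * predictors["SM7"].to_numpy(float)
            + c["nirv"] * predictors["NIRv"].to_numpy(float)
            - c["vpd30"] * predictors["VPD30"].to_numpy(float)
            + c["dl"] * predictors["DL"].to_numpy(float)
        )
        return np.clip(lfmc, *LFMC_CLIP)

    def bias_for(self, site_id: str, quantile: np.ndarray) -> np.ndarray:
        b = self.site_bias.get(site_id, 0.0)
        if callable(b):
            return np.asarray(b(quantile), dtype=float)
        return np.full_like(np.asarray(quantile, dtype=float), float(b))


def tail_heavy_bias(amplitude: float):
    """Quantile-dependent site bias: zero at the median, +/- amplitude at
    the distribution tails (wet-peak positive, dry-tail negative)."""

    def bias(q: np.ndarray) -> np.ndarray:
        return amplitude * 2.0 * (np.asarray(q, dtype=float) - 0.5)

    return bias


def _smooth_field(rng: np.random.Generator, n_lat: int, n_lon: int, n_modes: int = 4) -> np.ndarray:
    """Smooth random surface in [0, 1] from a few low-order harmonics."""
    y = np.linspace(0, 1, n_lat)[:, None]
    x = np.linspace(0, 1, n_lon)[None, :]
    f = np.zeros((n_lat, n_lon))
    for _ in range(n_modes):
        fy, fx = rng.uniform(0.5, 2.0, 2)
        py, px = rng.uniform(0, 2 * np.pi, 2)
        f += rng.uniform(0.5, 1.0) * np.sin(2 * np.pi * fy * y + py) * np.sin(
            2 * np.pi * fx * x + px
        )
    f -= f.min()
    if f.max() > 0:
        f /= f.max()
    return f


def generate_domain(n_lat: int, n_lon: int, seed: int) -> DomainGrid:
    """A coastal mountain domain: smooth correlated elevation rising away
    from a masked western coastal strip.

    Deterministic per seed; at least one land and one sea cell for any
    ``n_lat, n_lon >= 4``.
    """
    if n_lat < 4 or n_lon < 4:
        raise ValueError("domain must be at least 4 x 4 cells")
    rng = np.random.default_rng(seed)
    # 1-km-class spacing in degrees, centered on the Santa Barbara coast area
    lats = 34.3 + 0.009 * np.arange(n_lat)
    lons = -120.2 + 0.011 * np.arange(n_lon)
    ramp = np.linspace(-80.0, 900.0, n_lon)[None, :]  # rises inland (eastward)
    bumps = 1400.0 * _smooth_field(rng, n_lat, n_lon)
    elevation = ramp + bumps * np.linspace(0.2, 1.0, n_lon)[None, :]
    elevation[:, 0] = np.minimum(elevation[:, 0], -5.0)  # guaranteed coastal strip
    land_mask = elevation > 0.0
    land_mask[:, -1] = True
    elevation[:, -1] = np.maximum(elevation[:, -1], 50.0)
    elevation[~land_mask] = np.minimum(elevation[~land_mask], -1.0)
    return DomainGrid(lats=lats, lons=lons, elevation=elevation, land_mask=land_mask)


def generate_forcing(grid: DomainGrid, start, end, seed: int) -> xr.Dataset:
    """Daily meteorological forcing over the grid (the NWP stand-in).

    Returns an xarray Dataset with dims (time, lat, lon) and variables
    P (mm/d), T (degC), RH (%), SW (W m-2), SM (m3 m-3), AET (mm/d),
    Psfc (kPa), Rn (W m-2), es/ea (kPa), u (m/s). The period must be at
    least 200 days so that 150-day lag features have headroom.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if (end - start).days < 200:
        raise ValueError("forcing period must span at least 200 days (150-day lags)")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, end, freq="D")
    nt = len(dates)
    n_lat, n_lon = grid.shape
    doy = dates.dayofyear.to_numpy(float)
    elev = np.maximum(grid.elevation, 0.0)  # sea cells treated as sea level

    # --- temperature: seasonal cycle + lapse rate + regional AR(1) anomaly
    t_season = 15.0 + 8.0 * np.sin(2 * np.pi * (doy - 110.0) / 365.25)
    anom = np.empty(nt)
    anom[0] = rng.normal(0, 1.5)
    eps = rng.normal(0, 1.5, nt)
    for t in range(1, nt):
        anom[t] = 0.8 * anom[t - 1] + eps[t]
    T = (
        t_season[:, None, None]
        + anom[:, None, None]
        - 6.5 * elev[None, :, :] / 1000.0
        + rng.normal(0, 0.4, (nt, n_lat, n_lon))
    )

    # --- precipitation: winter-concentrated regional storm process
    wet_weight = 0.5 * (1 + np.cos(2 * np.pi * (doy - 15.0) / 365.25))
    p_storm = 0.02 + 0.26 * wet_weight
    storm_day = rng.random(nt) < p_storm
    storm_amount = np.where(storm_day, rng.gamma(0.9, 13.0, nt), 0.0)
    orog = 0.7 + 0.8 * _smooth_field(rng, n_lat, n_lon)
    cell_noise = rng.lognormal(0.0, 0.25, (nt, n_lat, n_lon))
    P = storm_amount[:, None, None] * orog[None, :, :] * cell_noise
    P[~storm_day] = 0.0

    # --- shortwave: annual cycle, reduced on storm (cloudy) days
    sw_clear = 250.0 + 120.0 * np.sin(2 * np.pi * (doy - 81.0) / 365.25)
    cloud_factor = np.where(storm_day, 0.35, 1.0)
    SW = np.clip(
        (sw_clear * cloud_factor)[:, None, None]
        * rng.uniform(0.92, 1.08, (nt, n_lat, n_lon)),
        20.0,
        None,
    )

    # --- humidity anti-correlated with temperature, boosted on storm days
    RH = np.clip(
        85.0
        - 1.3 * (T - 5.0)
        + 18.0 * storm_day[:, None, None]
        + rng.normal(0, 5.0, (nt, n_lat, n_lon)),
        12.0,
        100.0,
    )
    es = 0.6108 * np.exp(17.27 * T / (T + 237.3))
    ea = es * RH / 100.0

    u = np.abs(
        2.5
        + 1.0 * np.sin(2 * np.pi * doy / 365.25)[:, None, None]
        + rng.normal(0, 1.1, (nt, n_lat, n_lon))
    ) + 0.3
    Psfc = 101.3 * ((293.0 - 0.0065 * elev) / 293.0) ** 5.26
    Psfc = Psfc[None, :, :] + rng.normal(0, 0.1, (nt, n_lat, n_lon))
    Rn = np.clip(0.77 * SW - 35.0, -20.0, None)

    eto = penman_monteith_eto(T=T, u=u, es=es, ea=ea, Rn=Rn, Psfc=Psfc)

    # --- leaky-bucket soil water: capacity 150 mm of plant-available water
    capacity = 150.0
    W = np.empty((nt, n_lat, n_lon))
    AET = np.empty((nt, n_lat, n_lon))
    w_prev = np.full((n_lat, n_lon), 0.5 * capacity)
    for t in range(nt):
        aet = 0.9 * eto[t] * (w_prev / capacity) ** 0.7
        aet = np.minimum(aet, w_prev)
        w = np.clip(w_prev + P[t] - aet - 0.02 * w_prev, 0.0, capacity)
        AET[t] = aet
        W[t] = w
        w_prev = w
    SM = 0.05 + 0.40 * W / capacity

    data = {
        "P": P, "T": T, "RH": RH, "SW": SW, "SM": SM, "AET": AET,
        "Psfc": Psfc, "Rn": Rn, "es": es, "ea": ea, "u": u,
    }
    ds = xr.Dataset(
        {k: (("time", "lat", "lon"), v) for k, v in data.items()},
        coords={"time": dates, "lat": grid.lats, "lon": grid.lons},
    )
    ds.attrs["seed"] = int(seed)
    return ds


def _clean_nirv(grid: DomainGrid, rng: np.random.Generator, doy: np.ndarray) -> np.ndarray:
    """Smooth seasonal greenness truth, peaking in early spring."""
    base = 0.16 + 0.10 * _smooth_field(rng, *grid.shape)
    amp = 0.05 + 0.05 * _smooth_field(rng, *grid.shape)
    season = np.cos(2 * np.pi * (doy[:, None, None] - 100.0) / 365.25)
    return np.clip(base[None] + amp[None] * season, 0.05, 0.45)


def generate_scenes(
    grid: DomainGrid,
    start,
    end,
    revisit_days: int = 12,
    cloud_fraction: float = 0.3,
    seed: int = 0,
    reflectance_noise: float = 0.004,
) -> SceneStack:
    """Irregular cloudy optical scenes over a smooth seasonal greenness.

    A fraction ``cloud_fraction`` of cells per scene is flagged cloudy
    (bright reflectances); a subset of cloud-adjacent cells gets depressed
    NIR (shadows) and is truth-flagged but NOT flagged cloudy — exactly the
    contamination the shadow filter must catch.
    """
    if revisit_days < 1:
        raise ValueError("revisit_days must be >= 1")
    if not 0.0 <= cloud_fraction <= 1.0:
        raise ValueError("cloud_fraction must be within [0, 1]")
    rng = np.random.default_rng(seed)
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    base_dates = pd.date_range(start, end, freq=f"{revisit_days}D")
    keep = rng.random(len(base_dates)) > 0.08  # occasional missed acquisition
    jitter = rng.integers(0, max(revisit_days // 4, 1), len(base_dates))
    dates = pd.DatetimeIndex(
        sorted(set(d + pd.Timedelta(days=int(j)) for d, j, k in zip(base_dates, jitter, keep) if k))
    )
    nt = len(dates)
    n_lat, n_lon = grid.shape
    doy = dates.dayofyear.to_numpy(float)

    truth = _clean_nirv(grid, rng, doy)
    nir = 0.28 + 0.5 * truth
    ndvi = truth / nir
    red = nir * (1 - ndvi) / (1 + ndvi)
    if reflectance_noise > 0:
        nir = np.clip(nir + rng.normal(0, reflectance_noise, nir.shape), 0.01, 1.0)
        red = np.clip(red + rng.normal(0, reflectance_noise, red.shape), 0.005, 1.0)

    cloud = rng.random((nt, n_lat, n_lon)) < cloud_fraction
    shifted = np.zeros_like(cloud)
    shifted[:, 1:, 1:] = cloud[:, :-1, :-1]  # shadow cast to the southeast
    shadow = shifted & ~cloud & (rng.random((nt, n_lat, n_lon)) < 0.7)

    nir = np.where(shadow, nir * 0.45, nir)
    red = np.where(shadow, red * 0.75, red)
    bright = rng.uniform(0.55, 0.85, (nt, n_lat, n_lon))
    nir = np.where(cloud, bright, nir)
    red = np.where(cloud, bright * rng.uniform(0.9, 1.0, (nt, n_lat, n_lon)), red)

    return SceneStack(
        dates=dates, red=red, nir=nir, cloud=cloud, shadow=shadow, truth_nirv=truth
    )


def make_sites(grid: DomainGrid, n_sites: int, seed: int, prefix: str = "site") -> list[SiteMeta]:
    """Place observation sites on distinct land cells, spread across the
    domain (sampled without replacement from land cells)."""
    rng = np.random.default_rng(seed)
    land = np.argwhere(grid.land_mask)
    # keep sites off the outermost ring so bilinear sampling is always in-hull
    interior = land[
        (land[:, 0] > 0)
        & (land[:, 0] < grid.shape[0] - 1)
        & (land[:, 1] > 0)
        & (land[:, 1] < grid.shape[1] - 1)
    ]
    pool = interior if len(interior) >= n_sites else land
    if n_sites > len(pool):
        raise ValueError(f"cannot place {n_sites} sites on {len(pool)} land cells")
    idx = rng.choice(len(pool), size=n_sites, replace=False)
    sites = []
    for k, (i, j) in enumerate(pool[idx]):
        sites.append(
            SiteMeta(
                site_id=f"{prefix}{k:02d}",
                lat=float(grid.lats[i]),
                lon=float(grid.lons[j]),
                elev=float(grid.elevation[i, j]),
            )
        )
    return sites


def observation_schedule(
    start, end, sites: list[SiteMeta], dropout: float, seed: int, jitter_days: int = 3
) -> pd.DataFrame:
    """Semi-monthly-ish sampling plan: each site is visited near each
    1st/15th step, with random dropout and a few days of date jitter."""
    rng = np.random.default_rng(seed)
    steps = semimonthly_steps(start, end)
    rows = []
    for site in sites:
        for step in steps:
            if rng.random() < dropout:
                continue
            date = step + pd.Timedelta(days=int(rng.integers(0, jitter_days + 1)))
            if date > pd.Timestamp(end):
                date = pd.Timestamp(end)
            rows.append({"site_id": site.site_id, "date": date})
    return pd.DataFrame(rows, columns=["site_id", "date"])


def sample_observations(
    truth: SyntheticTruth,
    predictors_at_sites: pd.DataFrame,
    sites: list[SiteMeta],
    dropout: float = 0.0,
    fuel_type: str = "chamise",
    grid: DomainGrid | None = None,
    duplicate_prob: float = 0.04,
    seed: int | None = None,
) -> pd.DataFrame:
    """Noisy, biased LFMC observations from the planted truth.

    ``predictors_at_sites`` holds one row per (site_id, date) with the
    predictor columns g() needs. obs = g(predictors) + site_bias + noise,
    clipped to [30, 300]. A small fraction of records is duplicated on the
    same day (with fresh noise) to exercise same-day deduplication.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    site_ids = {s.site_id for s in sites}
    if grid is not None:
        for s in sites:
            i, j = grid.cell_index(s.lat, s.lon)
            if not grid.contains(s.lat, s.lon) or not grid.land_mask[i, j]:
                raise ValueError(f"site {s.site_id} is not on a land cell of the grid")
    df = predictors_at_sites[predictors_at_sites["site_id"].isin(site_ids)].copy()
    if dropout > 0:
        df = df[rng.random(len(df)) >= dropout]
    if df.empty:
        return pd.DataFrame(
            columns=["site_id", "lat", "lon", "elev", "date", "fuel_type", "lfmc_percent"]
        )
    df = df.reset_index(drop=True)
    lfmc_true = truth.g(df)
    # empirical quantile of the true value within each site's own series
    q = np.empty(len(df))
    for sid, idx in df.groupby("site_id").groups.items():
        vals = lfmc_true[np.asarray(idx)]
        q[np.asarray(idx)] = pd.Series(vals).rank(pct=True).to_numpy()
    bias = np.concatenate(
        [
            truth.bias_for(sid, q[np.asarray(idx)])
            for sid, idx in df.groupby("site_id").groups.items()
        ]
    )
    order = np.concatenate([np.asarray(idx) for _, idx in df.groupby("site_id").groups.items()])
    bias_aligned = np.empty(len(df))
    bias_aligned[order] = bias
    noise = rng.normal(0, truth.noise_sd, len(df))
    obs = np.clip(lfmc_true + bias_aligned + noise, *LFMC_CLIP)

    meta = {s.site_id: s for s in sites}
    out = pd.DataFrame(
        {
            "site_id": df["site_id"].to_numpy(),
            "lat": [meta[s].lat for s in df["site_id"]],
            "lon": [meta[s].lon for s in df["site_id"]],
            "elev": [meta[s].elev for s in df["site_id"]],
            "date": pd.to_datetime(df["date"].to_numpy()),
            "fuel_type": fuel_type,
            "lfmc_percent": obs,
            "lfmc_true": lfmc_true,
        }
    )
    if duplicate_prob > 0 and len(out):
        dup_mask = rng.random(len(out)) < duplicate_prob
        dups = out[dup_mask].copy()
        dups["lfmc_percent"] = np.clip(
            dups["lfmc_true"] + bias_aligned[dup_mask] + rng.normal(0, truth.noise_sd, len(dups)),
            *LFMC_CLIP,
        )
        out = pd.concat([out, dups], ignore_index=True)
        out = out.sort_values(["site_id", "date"], kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# interchange writers

def write_forcing(met: xr.Dataset, path) -> None:
    met.to_netcdf(path, engine="scipy")


def read_forcing(path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()


def write_scenes(stack: SceneStack, outdir) -> Path:
    """Scenes as single-band TIFF rasters plus a CSV index.

    Each scene writes red/nir/cloud rasters; the index records date, paths
    and the grid's geotransform-style bounds (plain lat/lon raster — no
    projection metadata)."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, date in enumerate(stack.dates):
        tag = pd.Timestamp(date).strftime("%Y%m%d")
        paths = {}
        for band, arr in (("red", stack.red[k]), ("nir", stack.nir[k]), ("cloud", stack.cloud[k])):
            p = outdir / f"scene_{tag}_{band}.tif"
            tifffile.imwrite(p, arr.astype(np.float32))
            paths[band] = p.name
        rows.append({"date": pd.Timestamp(date).date().isoformat(), **paths})
    index = pd.DataFrame(rows)
    index.to_csv(outdir / "scene_index.csv", index=False)
    return outdir / "scene_index.csv"


def read_scenes(index_csv) -> SceneStack:
    import tifffile

    index_csv = Path(index_csv)
    index = pd.read_csv(index_csv)
    base = index_csv.parent
    red, nir, cloud = [], [], []
    for _, row in index.iterrows():
        red.append(tifffile.imread(base / row["red"]).astype(float))
        nir.append(tifffile.imread(base / row["nir"]).astype(float))
        cloud.append(tifffile.imread(base / row["cloud"]).astype(bool))
    dates = pd.DatetimeIndex(pd.to_datetime(index["date"]))
    red, nir, cloud = np.array(red), np.array(nir), np.array(cloud)
    empty = np.zeros_like(cloud)
    return SceneStack(
        dates=dates, red=red, nir=nir, cloud=cloud, shadow=empty, truth_nirv=np.full_like(red, np.nan)
    )
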