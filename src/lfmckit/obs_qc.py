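"""Quality control for live fuel moisture content observation tables.

LFMC observations arrive as long tables of (site, date, fuel type, LFMC %)
records collected by fire agencies. Before model training they are
harmonized (new-growth chamise relabeled as chamise), duplicate same-day
measurements averaged, and thin sites / thin fuel types dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Column names expected in an observation table.
OBS_COLUMNS = ["site_id", "date", "fuel_type", "lfmc_percent"]

#: Labels merged into the canonical "chamise" label. The distribution of
#: plain-"chamise" records matches typical new-growth values, so the
#: new-growth label is collapsed into it; old growth stays a separate fuel.
LABEL_MERGES = {"chamise new growth": "chamise"}


@dataclass
class SiteMeta:
    """Metadata for one observation site."""

    site_id: str
    lat: float
    lon: float
    elev: float
    n_obs: dict = field(default_factory=dict)  # per fuel type


def harmonize_labels(records: pd.DataFrame, merges: dict | None = None) -> pd.DataFrame:
    """Merge equivalent fuel-type labels (chamise new growth -> chamise)."""
    merges = LABEL_MERGES if merges is None else merges
    out = records.copy()
    if len(out):
        out["fuel_type"] = out["fuel_type"].replace(merges)
    return out


def collapse_same_day(records: pd.DataFrame) -> pd.DataFrame:
    """Average duplicate measurements of one fuel at one site on one day."""
    if records.empty:
        return records.copy()
    keys = ["site_id", "fuel_type", "date"]
    extra = [c for c in records.columns if c not in keys + ["lfmc_percent"]]
    agg = {"lfmc_percent": "mean", **{c: "first" for c in extra}}
    out = records.groupby(keys, as_index=False, sort=False).agg(agg)
    return out[list(records.columns)]


def filter_sites_and_fuels(
    records: pd.DataFrame,
    site_exclusions: list[str] | None = None,
    min_site_obs: int = 25,
    min_fuel_obs: int = 500,
) -> pd.DataFrame:
    """Drop excluded sites, thin sites (< min_site_obs records) and thin
    fuel types (<= min_fuel_obs records).

    Site exclusions are a manual quality-control list (judgment calls such
    as a site disagreeing with its spatial neighbors are not automated).
    Threshold semantics are strict on both sides: a site is kept only with
    at least ``min_site_obs`` records and a fuel type only with strictly
    more than ``min_fuel_obs``.
    """
    out = records.copy()
    if site_exclusions:
        out = out[~out["site_id"].isin(set(site_exclusions))]
    site_counts = out.groupby("site_id")["lfmc_percent"].count()
    keep_sites = site_counts[site_counts >= min_site_obs].index
    out = out[out["site_id"].isin(keep_sites)]
    fuel_counts = out.groupby("fuel_type")["lfmc_percent"].count()
    keep_fuels = fuel_counts[fuel_counts > min_fuel_obs].index
    out = out[out["fuel_type"].isin(keep_fuels)]
    if out.empty:
        warnings.warn("QC filtering removed every observation record", stacklevel=2)
    return out.reset_index(drop=True)


def qc_chain(
    records: pd.DataFrame,
    site_exclusions: list[str] | None = None,
    min_site_obs: int = 25,
    min_fuel_obs: int = 500,
) -> pd.DataFrame:
    """Full QC pipeline: harmonize labels, average duplicates, filter."""
    out = harmonize_labels(records)
    out = collapse_same_day(out)
    out = filter_sites_and_fuels(out, site_exclusions, min_site_obs, min_fuel_obs)
    logger.info("QC: %d -> %d records", len(records), len(out))
    return out


def qc_report(records: pd.DataFrame) -> pd.DataFrame:
    """Observation counts per fuel type per site."""
    return (
        records.groupby(["fuel_type", "site_id"])["lfmc_percent"]
        .agg(n_obs="count", mean_lfmc="mean")
        .reset_index()
    )


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    return df


def write_observations(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
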