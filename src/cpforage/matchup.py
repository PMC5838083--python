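"""Environmental matchup: join positions to gridded covariates.

Each presence or pseudoabsence daily position is joined to every
environmental covariate by averaging over a 1 degree x 1 degree box centred
on the position, using the time slice nearest to the position's date within
each variable's native temporal resolution window (1-8 days). Eddy kinetic
energy is computed cellwise from the geostrophic current components,
EKE = (u^2 + v^2)/2, before box averaging. Chl-a and EKE are log10
transformed and bathymetry SD square-root transformed; bathymetry stays in
negative metres below sea level.

Box membership uses cell centres and half-open intervals
[lon-b/2, lon+b/2) x [lat-b/2, lat+b/2) so edge counts are reproducible.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from ._geo import great_circle_km

logger = logging.getLogger(__name__)

#: covariates produced by build_matchup_table, on their transformed scales
COVARIATES = ["sst", "chl", "sla", "sla_sd", "sst_sd", "wind_v",
              "eke", "bathymetry", "bathymetry_sd"]

#: variables requiring a log10 transform (positive support)
LOG10_VARS = ("chl", "eke")
#: variables requiring a square-root transform
SQRT_VARS = ("bathymetry_sd",)


def compute_eke(u, v):
    """Eddy kinetic energy (u^2 + v^2)/2 from current components (cm/s)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    out = 0.5 * (u * u + v * v)
    return out if np.ndim(out) else float(out)


def eke_field(env: xr.Dataset) -> xr.DataArray:
    """Cellwise EKE field (cm^2/s^2) from the u, v components."""
    da = 0.5 * (env["u"] ** 2 + env["v"] ** 2)
    da.attrs = {"units": "cm2 s-2",
                "native_resolution_days": env["u"].attrs.get(
                    "native_resolution_days", 1)}
    da.name = "eke"
    return da


# ---------------------------------------------------------------------------
# Point and grid transformed lookups (shared with the synthetic truth)
# ---------------------------------------------------------------------------

def _transform(name, values):
    values = np.asarray(values, dtype=float)
    if name in LOG10_VARS:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(values > 0, np.log10(np.maximum(values, 1e-300)), np.nan)
    if name in SQRT_VARS:
        return np.sqrt(np.maximum(values, 0.0))
    return values


def _raw_grid(env: xr.Dataset, name: str, date) -> np.ndarray:
    if name == "eke":
        u = _raw_grid(env, "u", date)
        v = _raw_grid(env, "v", date)
        return 0.5 * (u * u + v * v)
    da = env[name]
    if "time" in da.dims:
        da = da.sel(time=np.datetime64(date), method="nearest")
    return da.values


def transformed_grid(env: xr.Dataset, name: str, date) -> np.ndarray:
    """Covariate grid at a date on the transformed scale (nearest slice)."""
    return _transform(name, _raw_grid(env, name, date))


def transformed_point(env: xr.Dataset, name: str, lons, lats, date):
    """Nearest-cell transformed covariate values at points."""
    grid = transformed_grid(env, name, date)
    glons = env["lon"].values
    glats = env["lat"].values
    i = np.clip(np.rint((np.asarray(lats, float) - glats[0]) /
                        (glats[1] - glats[0])).astype(int), 0, len(glats) - 1)
    j = np.clip(np.rint((np.asarray(lons, float) - glons[0]) /
                        (glons[1] - glons[0])).astype(int), 0, len(glons) - 1)
    return grid[i, j]


# ---------------------------------------------------------------------------
# Box-mean extraction
# ---------------------------------------------------------------------------

def _nearest_time_index(times: np.ndarray, date, window_days: float):
    dt = np.abs((times - np.datetime64(date)) / np.timedelta64(1, "D"))
    k = int(np.argmin(dt))
    if dt[k] > window_days:
        return None
    return k


def extract_box_mean(field: xr.DataArray, lon: float, lat: float, date=None,
                     box_deg: float = 1.0, time_window_days=None,
                     stat: str = "mean") -> float:
    """Mean of non-missing cells in the half-open box centred on a position.

    For dynamic fields the time slice nearest to ``date`` is used, provided
    it lies within ``time_window_days`` (default: the variable's
    native_resolution_days attribute, else 1 day); otherwise NaN is
    returned with a logged warning. ``stat="std"`` returns the spatial
    standard deviation instead (used as a fallback for SD layers).
    """
    lons = field["lon"].values
    lats = field["lat"].values
    vals = field.values
    if "time" in field.dims:
        if date is None:
            raise ValueError("date required for a time-dependent field")
        window = time_window_days
        if window is None:
            window = float(field.attrs.get("native_resolution_days", 1))
        k = _nearest_time_index(field["time"].values, date, window)
        if k is None:
            logger.warning("date %s outside temporal coverage of %s (window %s d)",
                           date, field.name, window)
            return float("nan")
        vals = vals[k]
    half = box_deg / 2.0
    j0 = np.searchsorted(lons, lon - half, side="left")
    j1 = np.searchsorted(lons, lon + half, side="left")
    i0 = np.searchsorted(lats, lat - half, side="left")
    i1 = np.searchsorted(lats, lat + half, side="left")
    sub = vals[i0:i1, j0:j1]
    if sub.size == 0 or np.all(np.isnan(sub)):
        return float("nan")
    if stat == "std":
        return float(np.nanstd(sub, ddof=0))
    return float(np.nanmean(sub))


# ---------------------------------------------------------------------------
# Transforms on a matchup table
# ---------------------------------------------------------------------------

def apply_transforms(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Apply the covariate transforms; exclude rows violating log domains.

    Chl-a -> log10(Chl-a), EKE -> log10(EKE), bathymetry SD -> sqrt.
    Rows with nonpositive Chl-a or EKE are excluded (logged), as the log is
    undefined there. Returns (transformed table, number excluded).
    """
    out = table.copy()
    bad = np.zeros(len(out), dtype=bool)
    for name in LOG10_VARS:
        if name in out.columns:
            vals = out[name].to_numpy(dtype=float)
            bad |= ~(vals > 0)
            out[name] = _transform(name, vals)
    for name in SQRT_VARS:
        if name in out.columns:
            out[name] = _transform(name, out[name].to_numpy(dtype=float))
    n_bad = int(bad.sum())
    if n_bad:
        logger.info("apply_transforms: excluded %d records with nonpositive "
                    "values under a log transform", n_bad)
    return out.loc[~bad].reset_index(drop=True), n_bad


# ---------------------------------------------------------------------------
# Matchup table
# ---------------------------------------------------------------------------

def build_matchup_table(positions: pd.DataFrame, fields: xr.Dataset,
                        colony: tuple[float, float], box_deg: float = 1.0,
                        max_excluded_frac: float = 0.5) -> pd.DataFrame:
    """Join daily positions to all covariates; one record per position.

    ``positions`` must have columns source (presence|pseudoabsence),
    animal_id, trip_id, date, lon, lat and may carry sim_id for
    pseudoabsences. Records with any missing covariate (or a nonpositive
    value under a log transform) are excluded and counted; more than
    ``max_excluded_frac`` exclusions raises (coverage mismatch).
    """
    req = {"source", "animal_id", "trip_id", "date", "lon", "lat"}
    missing = req - set(positions.columns)
    if missing:
        raise ValueError(f"positions table missing columns: {sorted(missing)}")

    dynamic = ["sst", "chl", "sla", "wind_v"]
    eke = eke_field(fields)
    n = len(positions)
    out = positions.reset_index(drop=True).copy()
    lons = out["lon"].to_numpy(float)
    lats = out["lat"].to_numpy(float)
    dates = pd.to_datetime(out["date"]).to_numpy()

    for name in dynamic:
        out[name] = [extract_box_mean(fields[name], lons[r], lats[r], dates[r],
                                      box_deg=box_deg) for r in range(n)]
    out["eke"] = [extract_box_mean(eke, lons[r], lats[r], dates[r],
                                   box_deg=box_deg) for r in range(n)]
    for name, base in (("sst_sd", "sst"), ("sla_sd", "sla")):
        if name in fields:
            out[name] = [extract_box_mean(fields[name], lons[r], lats[r],
                                          dates[r], box_deg=box_deg)
                         for r in range(n)]
        else:  # fallback: spatial SD of the base variable within the box
            out[name] = [extract_box_mean(fields[base], lons[r], lats[r],
                                          dates[r], box_deg=box_deg, stat="std")
                         for r in range(n)]
    for name in ("bathymetry", "bathymetry_sd"):
        out[name] = [extract_box_mean(fields[name], lons[r], lats[r],
                                      box_deg=box_deg) for r in range(n)]
    out["dist_colony"] = great_circle_km(lons, lats, colony[0], colony[1])

    missing_any = out[COVARIATES].isna().any(axis=1).to_numpy()
    n_missing = int(missing_any.sum())
    out = out.loc[~missing_any].reset_index(drop=True)
    out, n_domain = apply_transforms(out)
    n_excl = n_missing + n_domain
    logger.info("build_matchup_table: %d records, %d excluded "
                "(%d missing covariate, %d log-domain)",
                n, n_excl, n_missing, n_domain)
    if n and n_excl / n > max_excluded_frac:
        raise ValueError(f"{n_excl}/{n} records excluded: environmental "
                         "coverage does not match track extent")
    return out


def write_matchup_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_matchup_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df
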