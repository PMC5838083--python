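"""Daily habitat-suitability surfaces and seasonal composites.

For each cell of a 0.25 degree grid, covariates are sampled at the cell
centre with the same 1 degree box-mean operator and transforms used in
training, the fitted linear predictor is evaluated with the individual
effect at its population mean, and suitability is the inverse-logit
probability (0 = unsuitable, 1 = highly suitable). Daily surfaces average
into seasonal mean and standard-error maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .matchup import COVARIATES, _transform, eke_field, extract_box_mean
from .model import FitResult

GRID_STEP = 0.25


@dataclass
class PredictionSurface:
    date: np.datetime64
    suitability: xr.DataArray  # (lat, lon), NaN where masked

    @property
    def values(self) -> np.ndarray:
        return self.suitability.values


@dataclass
class SeasonalComposite:
    mean: xr.DataArray
    se: xr.DataArray
    n_days: xr.DataArray


def _prediction_grid(fields: xr.Dataset, grid_step: float):
    lon0, lon1 = float(fields["lon"].min()), float(fields["lon"].max())
    lat0, lat1 = float(fields["lat"].min()), float(fields["lat"].max())
    lons = np.arange(np.floor(lon0 / grid_step) * grid_step + grid_step / 2,
                     lon1, grid_step)
    lats = np.arange(np.floor(lat0 / grid_step) * grid_step + grid_step / 2,
                     lat1, grid_step)
    return lons, lats


def covariate_table_for_grid(fields: xr.Dataset, date, lons, lats,
                             covariates, box_deg: float = 1.0,
                             colony=None) -> pd.DataFrame:
    """Transformed covariates at cell centres via the matchup rules."""
    lon2, lat2 = np.meshgrid(lons, lats)
    flat_lon = lon2.ravel()
    flat_lat = lat2.ravel()
    need = set(covariates)
    raw: dict[str, np.ndarray] = {}
    eke = eke_field(fields) if "eke" in need else None
    for name in need:
        if name == "dist_colony":
            if colony is None:
                raise ValueError("colony coordinates required for dist_colony")
            from ._geo import great_circle_km
            raw[name] = great_circle_km(flat_lon, flat_lat, colony[0], colony[1])
            continue
        if name == "eke":
            fld = eke
        elif name in fields:
            fld = fields[name]
        else:
            raise ValueError(f"missing covariate layer: {name}")
        vals = np.array([extract_box_mean(
            fld, flat_lon[i], flat_lat[i],
            date if "time" in fld.dims else None, box_deg=box_deg)
            for i in range(flat_lon.size)])
        raw[name] = vals
    out = pd.DataFrame({"lon": flat_lon, "lat": flat_lat})
    for name in covariates:
        out[name] = _transform(name, raw[name])
    return out


def predict_daily(fit: FitResult, fields: xr.Dataset, date,
                  grid_step: float = GRID_STEP, box_deg: float = 1.0,
                  colony=None, rescale: bool = False) -> PredictionSurface:
    """Habitat-suitability surface for one day at 0.25 degree resolution.

    Land cells (bathymetry >= 0 at the cell centre's grid cell) and cells
    with any missing covariate are masked. ``rescale`` optionally min-max
    rescales the surface to span [0, 1] exactly.
    """
    date = np.datetime64(date)
    lons, lats = _prediction_grid(fields, grid_step)
    tab = covariate_table_for_grid(fields, date, lons, lats,
                                   fit.spec.covariates, box_deg=box_deg,
                                   colony=colony)
    ok = ~tab[fit.spec.covariates].isna().any(axis=1).to_numpy()
    suit = np.full(len(tab), np.nan)
    if ok.any():
        suit[ok] = fit.predict_probability(tab.loc[ok])
    suit = suit.reshape(len(lats), len(lons))

    from .synthetic import land_lookup
    land = land_lookup(fields)
    lon2, lat2 = np.meshgrid(lons, lats)
    suit[land(lon2.ravel(), lat2.ravel()).reshape(suit.shape)] = np.nan
    if rescale:
        lo, hi = np.nanmin(suit), np.nanmax(suit)
        if hi > lo:
            suit = (suit - lo) / (hi - lo)
    da = xr.DataArray(suit, coords={"lat": lats, "lon": lons},
                      dims=("lat", "lon"), name="suitability",
                      attrs={"date": str(date), "long_name":
                             "relative habitat suitability"})
    return PredictionSurface(date=date, suitability=da)


def seasonal_composite(surfaces: list[PredictionSurface]) -> SeasonalComposite:
    """Cellwise mean, standard error and day count over daily surfaces."""
    if len(surfaces) < 2:
        raise ValueError("need at least 2 surfaces to composite")
    ref = surfaces[0].suitability
    for s in surfaces[1:]:
        if (s.suitability.shape != ref.shape
                or not np.allclose(s.suitability["lon"], ref["lon"])
                or not np.allclose(s.suitability["lat"], ref["lat"])):
            raise ValueError("surfaces are not on identical grids")
    stack = np.stack([s.values for s in surfaces])
    n = np.sum(~np.isnan(stack), axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd = np.full_like(mean, np.nan)
        multi = n > 1
        sd[multi] = np.nanstd(stack, axis=0, ddof=1)[multi]
        se = sd / np.sqrt(np.maximum(n, 1.0))
    se[n == 1] = 0.0
    mean[n == 0] = np.nan
    se[n == 0] = np.nan
    coords = {"lat": ref["lat"], "lon": ref["lon"]}
    return SeasonalComposite(
        mean=xr.DataArray(mean, coords=coords, dims=("lat", "lon"), name="mean"),
        se=xr.DataArray(se, coords=coords, dims=("lat", "lon"), name="se"),
        n_days=xr.DataArray(n, coords=coords, dims=("lat", "lon"), name="n_days"))


def composite_to_netcdf(comp: SeasonalComposite, path) -> None:
    ds = xr.Dataset({"mean_suitability": comp.mean, "se_suitability": comp.se,
                     "n_days": comp.n_days})
    ds.to_netcdf(path, engine="scipy")


def surface_png(surface_or_composite, path, title: str = "") -> None:
    """Quick-look map of a surface or composite mean."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    da = (surface_or_composite.suitability
          if isinstance(surface_or_composite, PredictionSurface)
          else surface_or_composite.mean)
    fig, ax = plt.subplots(figsize=(6, 5))
    m = ax.pcolormesh(da["lon"], da["lat"], da.values, vmin=0, vmax=1,
                      cmap="viridis")
    fig.colorbar(m, ax=ax, label="suitability")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)
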