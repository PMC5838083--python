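"""Synthetic environment and central-place forager track generation.

This module builds a self-contained, ground-truthed test bed for the
habitat-suitability pipeline: winter eastern-boundary-upwelling-like
environmental fields on a regular grid (cool upwelled SST band inshore,
chlorophyll anticorrelated with SST, mesoscale eddies in the sea-level
anomaly field with rotational geostrophic currents, a shelf-to-abyss
bathymetry off a straight meridional coast), and preference-biased
out-and-back foraging trips from a fixed rookery.

Tracks are biased correlated walks: at each sub-daily step the heading is
chosen among candidate destinations with probability proportional to
exp(eta), where eta is the "truth" habitat preference evaluated at the
candidate. A homeward drift is ramped in over the second half of each trip
so that every trip returns to the rookery, reproducing the out-and-back
structure that trip segmentation and phase splitting assume.

All randomness derives from a single integer seed through
``numpy.random.SeedSequence.spawn`` (one child stream per field / per
individual), so identical seeds give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import uniform_filter
from scipy.special import expit

from ._geo import destination, great_circle_km, initial_bearing_deg

KM_PER_DEG = 111.32


# ---------------------------------------------------------------------------
# Scenario and truth definitions
# ---------------------------------------------------------------------------

@dataclass
class EnvScenario:
    """Parameters of the synthetic winter coastal-upwelling environment.

    Defaults emulate a California Current-like winter domain: a 5 degree x
    4 degree box with land along the eastern edge, daily dynamic fields
    over three winter months, and a handful of mesoscale eddies.
    """

    lon_range: tuple[float, float] = (-124.0, -119.0)
    lat_range: tuple[float, float] = (32.0, 36.0)
    grid_step: float = 0.1
    date_range: tuple[str, str] = ("2006-11-01", "2007-02-28")
    n_eddies: int = 6
    eddy_amplitude: float = 8.0      # cm
    eddy_radius_km: float = 60.0
    eddy_drift_deg_per_day: float = -0.02
    sst_inshore: float = 13.0        # deg C
    sst_offshore: float = 17.0       # deg C
    sst_decay_deg: float = 1.2       # e-folding scale of the coastal band
    sst_lat_weight: float = 0.5      # share of the SST signal that is meridional
    sst_patch_sd: float = 0.12       # mesoscale SST texture, fraction of range
    sst_front_offset_deg: float = 0.0  # >0 puts the cold core on an offshore front
    sst_front_width_deg: float = 0.35
    chl_base_log10: float = 0.3      # log10 mg/m3 at reference SST
    chl_sst_slope: float = -0.25     # log10 mg/m3 per deg C
    chl_ref_sst: float = 15.0
    chl_pattern_sd: float = 0.25     # log10 mg/m3, SST-independent structure
    wind_v_mean: float = -4.0        # m/s, equatorward = upwelling-favourable
    land_width_deg: float = 0.5
    abyss_depth_m: float = 4000.0
    abyss_scale_deg: float = 1.2
    geostrophic_scale: float = 150.0  # (cm/s) per (cm/km) of SLA slope
    noise_sd: dict[str, float] = field(default_factory=lambda: {
        "sst": 0.15, "chl": 0.05, "sla": 0.3, "wind_v": 1.0})
    seed: int = 0

    def validate(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.lon_range[1] <= self.lon_range[0] or self.lat_range[1] <= self.lat_range[0]:
            raise ValueError("lon/lat ranges must be non-degenerate")
        t0, t1 = np.datetime64(self.date_range[0]), np.datetime64(self.date_range[1])
        if t1 < t0:
            raise ValueError("date_range must span at least one day")
        if self.n_eddies < 0:
            raise ValueError("n_eddies must be >= 0")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be >= 0")

    @property
    def coast_lon(self) -> float:
        return self.lon_range[1] - self.land_width_deg


@dataclass
class TruthPreference:
    """Known habitat preference used to bias synthetic tracks.

    ``terms`` maps a covariate name (on its transformed scale, e.g. chl is
    log10 mg/m3) to a response shape: ``("linear", (b,))``,
    ``("quadratic", (b1, b2))`` or ``("gaussian", (height, center, width))``.
    """

    intercept: float = 0.0
    terms: dict[str, tuple[str, tuple[float, ...]]] = field(default_factory=dict)

    def term_value(self, name: str, x):
        shape, coefs = self.terms[name]
        x = np.asarray(x, dtype=float)
        if shape == "linear":
            return coefs[0] * x
        if shape == "quadratic":
            return coefs[0] * x + coefs[1] * x ** 2
        if shape == "gaussian":
            h, c, w = coefs
            return h * np.exp(-0.5 * ((x - c) / w) ** 2)
        raise ValueError(f"unknown response shape {shape!r}")

    def linear_predictor(self, covariates: dict[str, np.ndarray]):
        eta = np.asarray(self.intercept, dtype=float)
        for name in self.terms:
            if name not in covariates:
                raise KeyError(f"truth covariate {name!r} not available")
            eta = eta + self.term_value(name, covariates[name])
        return eta


# ---------------------------------------------------------------------------
# Environmental fields
# ---------------------------------------------------------------------------

def _rolling_std(arr: np.ndarray, size: int = 3) -> np.ndarray:
    """Local spatial standard deviation over a size x size window."""
    m = uniform_filter(arr, size=size, mode="nearest")
    m2 = uniform_filter(arr * arr, size=size, mode="nearest")
    return np.sqrt(np.maximum(m2 - m * m, 0.0))


def _eddy_fields(scenario, rng, lons, lats, days_since_start):
    """SLA (cm) and geostrophic u, v (cm/s) from drifting Gaussian eddies.

    u and v are the rotational flow of the anomaly surface:
    u = -c * dSLA/dy, v = c * dSLA/dx, evaluated analytically.
    """
    nt = len(days_since_start)
    lon2, lat2 = np.meshgrid(lons, lats)
    sla = np.zeros((nt, len(lats), len(lons)))
    u = np.zeros_like(sla)
    v = np.zeros_like(sla)
    sea_lon_max = scenario.coast_lon - 0.3
    for k in range(scenario.n_eddies):
        clon = rng.uniform(scenario.lon_range[0] + 0.5, sea_lon_max)
        clat = rng.uniform(scenario.lat_range[0] + 0.3, scenario.lat_range[1] - 0.3)
        radius = scenario.eddy_radius_km * rng.uniform(0.6, 1.4)
        amp = scenario.eddy_amplitude * rng.uniform(0.5, 1.0) * (1 if k % 2 == 0 else -1)
        for it, t in enumerate(days_since_start):
            cl = clon + scenario.eddy_drift_deg_per_day * t
            dx = (lon2 - cl) * KM_PER_DEG * np.cos(np.radians(lat2))
            dy = (lat2 - clat) * KM_PER_DEG
            g = amp * np.exp(-0.5 * (dx * dx + dy * dy) / radius ** 2)
            sla[it] += g
            # dSLA/dx = -g*dx/r^2, dSLA/dy = -g*dy/r^2  (per km)
            u[it] += scenario.geostrophic_scale * g * dy / radius ** 2
            v[it] += -scenario.geostrophic_scale * g * dx / radius ** 2
    return sla, u, v


def generate_env_fields(scenario: EnvScenario) -> xr.Dataset:
    """Generate the gridded environmental field set for a scenario.

    Returns an xarray Dataset with dynamic daily variables (sst, chl, sla,
    u, v, wind_v, sst_sd, sla_sd) on (time, lat, lon) and static bathymetry
    and bathymetry_sd on (lat, lon). Bathymetry is negative below sea level;
    cells with bathymetry >= 0 are land (the eastern strip).
    """
    scenario.validate()
    step = scenario.grid_step
    lons = np.arange(scenario.lon_range[0] + step / 2, scenario.lon_range[1], step)
    lats = np.arange(scenario.lat_range[0] + step / 2, scenario.lat_range[1], step)
    if len(lons) < 3 or len(lats) < 3:
        raise ValueError("degenerate grid: fewer than 3 cells along an axis")
    t0 = np.datetime64(scenario.date_range[0])
    t1 = np.datetime64(scenario.date_range[1])
    times = np.arange(t0, t1 + np.timedelta64(1, "D"), np.timedelta64(1, "D"))
    days = (times - times[0]) / np.timedelta64(1, "D")

    # all fields are generated on a one-cell halo and cropped at the end, so
    # local-window statistics (the SD layers) are free of array-edge bias
    lons_full = np.concatenate([[lons[0] - step], lons, [lons[-1] + step]])
    lats_full = np.concatenate([[lats[0] - step], lats, [lats[-1] + step]])

    children = np.random.SeedSequence(scenario.seed).spawn(6)
    rng_eddy, rng_sst, rng_chl, rng_sla, rng_wind, rng_bathy = (
        np.random.default_rng(c) for c in children)

    nt, ny, nx = len(times), len(lats_full), len(lons_full)
    lon2 = np.broadcast_to(lons_full, (ny, nx))

    # bathymetry: straight meridional coast, land strip to the east
    d_coast = scenario.coast_lon - lon2  # degrees offshore (>0 at sea)
    sea = d_coast > 0
    depth = -scenario.abyss_depth_m * (1.0 - np.exp(-d_coast / scenario.abyss_scale_deg))
    elev_land = 10.0 + 500.0 * (-d_coast)
    bathy = np.where(sea, depth, elev_land)
    roughness = np.abs(rng_bathy.normal(0.0, 1.0, size=bathy.shape))
    bathy_sd = _rolling_std(bathy) * (0.5 + 0.5 * roughness)

    # SST: bounded interpolation between inshore and offshore end members.
    # The upwelling band widens poleward and its intensity pulses over a
    # ~45-day cycle with a latitude-dependent lag, so SST is not a pure
    # function of distance from the coast (keeps it separable from depth).
    lat2 = np.broadcast_to(lats_full[:, None], (ny, nx))
    lat_frac = (lat2 - lats_full[0]) / max(lats_full[-1] - lats_full[0], 1e-9)
    decay = scenario.sst_decay_deg * (0.5 + lat_frac)
    if scenario.sst_front_offset_deg > 0:
        # cold core on an upwelling front offshore of the coast: cross-shore
        # but non-monotone in distance, so thermally distinct from depth
        w_space = np.exp(-0.5 * ((np.maximum(d_coast, 0.0)
                                  - scenario.sst_front_offset_deg)
                                 / scenario.sst_front_width_deg) ** 2)
    else:
        w_space = np.exp(-np.maximum(d_coast, 0.0) / decay)
    # blend the cross-shore band with a poleward cooling gradient; winter
    # eastern-boundary SST has a strong along-coast component, and it keeps
    # the thermal field separable from depth (which is purely cross-shore)
    a = scenario.sst_lat_weight
    w_struct = (1.0 - a) * w_space + a * lat_frac
    t_frac = np.asarray(days, dtype=float)
    intensity = 0.6 + 0.4 * np.cos(2 * np.pi * (t_frac[:, None, None] / 45.0)
                                   + np.pi * lat_frac[None])
    # mesoscale thermal texture: slowly-drifting Fourier patches (filaments,
    # eddy-scale anomalies); clipping keeps SST within its end members
    xg = np.broadcast_to((lons_full - lons_full[0])
                         / (lons_full[-1] - lons_full[0]), (ny, nx))
    yg = np.broadcast_to(((lats_full - lats_full[0])
                          / (lats_full[-1] - lats_full[0]))[:, None], (ny, nx))
    patch = np.zeros((nt, ny, nx))
    for _ in range(6):
        kx = rng_sst.integers(2, 7)
        ky = rng_sst.integers(2, 7)
        ph = rng_sst.uniform(0, 2 * np.pi)
        om = rng_sst.uniform(-1.0, 1.0) * 2 * np.pi / 60.0  # ~60-day evolution
        patch += np.cos(2 * np.pi * (kx * xg + ky * yg)[None] + ph
                        + om * t_frac[:, None, None])
    patch *= scenario.sst_patch_sd / np.sqrt(6.0)
    w = np.clip(intensity * w_struct[None] + patch, 0.0, 1.0)
    sst = (scenario.sst_offshore
           + (scenario.sst_inshore - scenario.sst_offshore) * w
           + rng_sst.normal(0.0, scenario.noise_sd.get("sst", 0.0),
                            size=(nt, ny, nx)))

    # Chl-a: anticorrelated with SST but not a deterministic function of it —
    # an independent low-order Fourier "productivity patch" pattern keeps the
    # two covariates statistically separable, as in real ocean-colour fields
    xfrac = np.broadcast_to((lons_full - lons_full[0])
                            / (lons_full[-1] - lons_full[0]), (ny, nx))
    yfrac = np.broadcast_to(((lats_full - lats_full[0])
                             / (lats_full[-1] - lats_full[0]))[:, None], (ny, nx))
    pattern = np.zeros((ny, nx))
    for _ in range(6):
        kx = rng_chl.integers(1, 4)
        ky = rng_chl.integers(1, 4)
        ph = rng_chl.uniform(0, 2 * np.pi)
        pattern += np.cos(2 * np.pi * (kx * xfrac + ky * yfrac) + ph)
    pattern *= scenario.chl_pattern_sd / np.sqrt(6.0)
    log_chl = (scenario.chl_base_log10
               + scenario.chl_sst_slope * (sst - scenario.chl_ref_sst)
               + pattern[None]
               + rng_chl.normal(0.0, scenario.noise_sd.get("chl", 0.0), size=sst.shape))
    chl = 10.0 ** log_chl

    sla, u, v = _eddy_fields(scenario, rng_eddy, lons_full, lats_full, days)
    sla = sla + rng_sla.normal(0.0, scenario.noise_sd.get("sla", 0.0), size=sla.shape)
    # optional unstructured current background (turbulence floor for EKE)
    u = u + rng_sla.normal(0.0, scenario.noise_sd.get("u", 0.0), size=u.shape)
    v = v + rng_sla.normal(0.0, scenario.noise_sd.get("v", 0.0), size=v.shape)

    wind_v = scenario.wind_v_mean + rng_wind.normal(
        0.0, scenario.noise_sd.get("wind_v", 0.0), size=(nt, ny, nx))

    sst_sd = np.stack([_rolling_std(sst[t]) for t in range(nt)])
    sla_sd = np.stack([_rolling_std(sla[t]) for t in range(nt)])

    # crop the halo
    crop = (slice(None), slice(1, -1), slice(1, -1))
    sst, chl, sla, u, v, wind_v, sst_sd, sla_sd = (
        a[crop] for a in (sst, chl, sla, u, v, wind_v, sst_sd, sla_sd))
    bathy = bathy[1:-1, 1:-1]
    bathy_sd = bathy_sd[1:-1, 1:-1]

    coords = {"time": times, "lat": lats, "lon": lons}
    dyn = ("time", "lat", "lon")
    ds = xr.Dataset(
        {
            "sst": (dyn, sst, {"units": "degC", "native_resolution_days": 1}),
            "chl": (dyn, chl, {"units": "mg m-3", "native_resolution_days": 8}),
            "sla": (dyn, sla, {"units": "cm", "native_resolution_days": 1}),
            "u": (dyn, u, {"units": "cm s-1", "native_resolution_days": 1}),
            "v": (dyn, v, {"units": "cm s-1", "native_resolution_days": 1}),
            "wind_v": (dyn, wind_v, {"units": "m s-1", "native_resolution_days": 1}),
            "sst_sd": (dyn, sst_sd, {"units": "degC", "native_resolution_days": 8}),
            "sla_sd": (dyn, sla_sd, {"units": "cm", "native_resolution_days": 8}),
            "bathymetry": (("lat", "lon"), bathy, {"units": "m",
                                                   "positive_is_land": 1}),
            "bathymetry_sd": (("lat", "lon"), bathy_sd, {"units": "m"}),
        },
        coords=coords,
        attrs={"Conventions": "CF-1.8", "coast_lon": scenario.coast_lon},
    )
    return ds


def land_lookup(env: xr.Dataset):
    """Vectorised land test by nearest grid cell: bathymetry/elevation >= 0.

    Points outside the grid are treated as land (impassable).
    """
    lons = env["lon"].values
    lats = env["lat"].values
    bathy = env["bathymetry"].values
    step_lon = lons[1] - lons[0]
    step_lat = lats[1] - lats[0]

    def is_land(lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        i = np.rint((lat - lats[0]) / step_lat).astype(int)
        j = np.rint((lon - lons[0]) / step_lon).astype(int)
        outside = (i < 0) | (i >= len(lats)) | (j < 0) | (j >= len(lons))
        i = np.clip(i, 0, len(lats) - 1)
        j = np.clip(j, 0, len(lons) - 1)
        land = bathy[i, j] >= 0.0
        out = land | outside
        return out if np.ndim(lon) else bool(out)

    return is_land


def write_env_netcdf(env: xr.Dataset, path) -> None:
    """Write the field set as CF NetCDF (classic format via the scipy engine)."""
    enc = {name: {"dtype": "float64"} for name in env.data_vars}
    env.to_netcdf(path, engine="scipy", encoding=enc)


def read_env_netcdf(path) -> xr.Dataset:
    return xr.load_dataset(path, engine="scipy")


# ---------------------------------------------------------------------------
# Truth evaluation
# ---------------------------------------------------------------------------

def _covariate_grids(env: xr.Dataset, names, date) -> dict[str, np.ndarray]:
    """Transformed covariate grids at a date (nearest time slice)."""
    from .matchup import transformed_grid  # local import to avoid cycle at import time
    return {name: transformed_grid(env, name, date) for name in names}


def truth_surface(env: xr.Dataset, truth: TruthPreference, date) -> xr.DataArray:
    """Inverse-logit of the truth linear predictor on the env grid.

    Land cells are masked (NaN). Raises KeyError for unknown covariates.
    """
    date = np.datetime64(date)
    t0, t1 = env["time"].values[0], env["time"].values[-1]
    if date < t0 or date > t1:
        raise ValueError(f"date {date} outside field coverage [{t0}, {t1}]")
    grids = _covariate_grids(env, list(truth.terms), date)
    eta = truth.linear_predictor(grids)
    eta = np.broadcast_to(np.asarray(eta, dtype=float),
                          env["bathymetry"].shape).copy()
    surf = expit(eta)
    surf[env["bathymetry"].values >= 0] = np.nan
    return xr.DataArray(surf, coords={"lat": env["lat"], "lon": env["lon"]},
                        dims=("lat", "lon"), name="truth_suitability")


# ---------------------------------------------------------------------------
# Track generation
# ---------------------------------------------------------------------------

_HEADING_OFFSETS = np.arange(-180.0, 180.0, 15.0)


def _truth_eta_at(env, truth, lons, lats, date):
    from .matchup import transformed_point
    cov = {name: transformed_point(env, name, lons, lats, date)
           for name in truth.terms}
    return truth.linear_predictor(cov)


def _simulate_trip(env, truth, rookery, is_land, rng, start_time, duration_days,
                   steps_per_day, mean_step_km, home_bias=8.0, away_bias=4.0):
    """One out-and-back trip; returns (timestamps, lons, lats) excluding start."""
    n_steps = int(round(duration_days * steps_per_day))
    dt = np.timedelta64(int(24 * 3600 / steps_per_day), "s")
    lon, lat = rookery
    heading = rng.uniform(0.0, 360.0)
    ts, xs, ys = [], [], []
    t = start_time
    arrived = False
    escaped = False  # has left the rookery neighbourhood at least once
    forced = False   # forced return latches once entered
    for j in range(n_steps):
        phase = j / n_steps
        step_km = min(rng.gamma(4.0, mean_step_km / 4.0), 25.0)
        dist_home = great_circle_km(lon, lat, *rookery)
        escaped = escaped or dist_home > 10.0
        steps_left = n_steps - j
        # forced return: head straight home once the remaining time requires it
        if phase > 0.5 and (forced or dist_home > (steps_left - 1) * mean_step_km * 0.8):
            forced = True
            brg = initial_bearing_deg(lon, lat, *rookery)
            step = min(dist_home, mean_step_km * 1.2)
            lon, lat = destination(lon, lat, brg, step)
            if great_circle_km(lon, lat, *rookery) < 1.0 or step >= dist_home:
                lon, lat = rookery
                arrived = True
            heading = brg
        else:
            cand_brg = (heading + _HEADING_OFFSETS) % 360.0
            clon, clat = destination(lon, lat, cand_brg, step_km)
            mlon, mlat = destination(lon, lat, cand_brg, step_km / 2.0)
            valid = ~(is_land(clon, clat) | is_land(mlon, mlat))
            if escaped:
                # keep mid-trip steps (endpoints and midpoints) outside the
                # rookery neighbourhood so neither a sub-daily position nor a
                # daily interpolate between two of them can fall inside the
                # haul-out detection radius and split the trip; the only way
                # back inside is the forced return above
                valid &= great_circle_km(clon, clat, *rookery) > 10.0
                valid &= great_circle_km(mlon, mlat, *rookery) > 10.0
            if not np.any(valid):
                brg = initial_bearing_deg(lon, lat, *rookery)
                lon, lat = destination(lon, lat, brg, step_km)
                heading = brg
            else:
                date = t.astype("datetime64[D]")
                # preference is evaluated at a look-ahead point beyond the
                # step itself: the walker responds to the broader-scale
                # field in its heading choice, not only the 15 km locale
                llon, llat = destination(lon, lat, cand_brg, 5.0 * step_km)
                eta = _truth_eta_at(env, truth, llon, llat, date)
                eta = np.where(np.isfinite(eta), eta, -50.0)
                home_brg = initial_bearing_deg(lon, lat, *rookery)
                align = np.cos(np.radians(cand_brg - home_brg))
                if phase < 0.2:
                    hw = -away_bias
                elif phase < 0.5:
                    hw = -away_bias if dist_home < 10.0 else 0.0
                else:
                    hw = home_bias * ((phase - 0.5) / 0.5) ** 2
                score = eta + hw * align
                score[~valid] = -np.inf
                score = score - np.max(score[valid])
                p = np.exp(score)
                p /= p.sum()
                k = rng.choice(len(cand_brg), p=p)
                heading = cand_brg[k]
                lon, lat = float(clon[k]), float(clat[k])
            # early homecoming counts as the end of the trip; the 5 km
            # threshold matches the default haul-out radius so a returning
            # walker cannot linger inside it and split the trip in two
            if phase > 0.5 and great_circle_km(lon, lat, *rookery) < 5.0:
                lon, lat = rookery
                arrived = True
        t = t + dt
        ts.append(t)
        xs.append(lon)
        ys.append(lat)
        if arrived:
            break
    if not arrived:  # close the loop at the rookery
        t = t + dt
        ts.append(t)
        xs.append(rookery[0])
        ys.append(rookery[1])
    return ts, xs, ys


def generate_tracks(env: xr.Dataset, rookery: tuple[float, float],
                    truth: TruthPreference, n_individuals: int,
                    trips_per_individual: int, seed: int,
                    steps_per_day: int = 4, mean_step_km: float = 15.0,
                    mean_trip_days: float = 8.0, trip_sigma: float = 0.4,
                    trip_day_range: tuple[float, float] = (2.0, 23.0),
                    jitter_km: float = 0.0) -> pd.DataFrame:
    """Generate preference-biased central-place forager tracks.

    Each individual alternates rookery haul-outs (1.5-3 days) with at-sea
    trips whose durations are lognormal (median ``mean_trip_days``) clipped
    to ``trip_day_range``. Returns a RawTrack table with columns
    animal_id, timestamp, lon, lat, lc.
    """
    is_land = land_lookup(env)
    lon_r, lat_r = rookery
    lons, lats = env["lon"].values, env["lat"].values
    if not (lons[0] <= lon_r <= lons[-1] and lats[0] <= lat_r <= lats[-1]):
        raise ValueError("rookery outside the environmental grid")
    if is_land(lon_r, lat_r):
        raise ValueError("rookery must be on a sea cell adjacent to land")

    children = np.random.SeedSequence(seed).spawn(n_individuals)
    t_start = env["time"].values[0].astype("datetime64[s]")
    t_end = env["time"].values[-1].astype("datetime64[s]")
    dt = np.timedelta64(int(24 * 3600 / steps_per_day), "s")
    rows = []
    for i in range(n_individuals):
        rng = np.random.default_rng(children[i])
        animal = f"A{i:02d}"
        t = t_start + np.timedelta64(int(rng.uniform(2, 12) * 3600), "s")

        def emit_haulout(t, days, rng=rng, animal=animal):
            n = int(round(days * steps_per_day))
            for _ in range(n):
                rows.append((animal, t, lon_r, lat_r))
                t = t + dt
            return t

        t = emit_haulout(t, rng.uniform(1.5, 2.5))
        for _k in range(trips_per_individual):
            dur = float(np.clip(rng.lognormal(np.log(mean_trip_days), trip_sigma),
                                *trip_day_range))
            # clip to the remaining schedule (reserve the closing haul-out)
            remaining = (t_end - t) / np.timedelta64(1, "D") - 3.0
            if remaining < trip_day_range[0]:
                raise ValueError("track schedule exceeds field temporal "
                                 "coverage; shorten trips or extend date_range")
            dur = min(dur, remaining)
            ts, xs, ys = _simulate_trip(env, truth, rookery, is_land, rng, t,
                                        dur, steps_per_day, mean_step_km)
            for tt, x, y in zip(ts, xs, ys):
                rows.append((animal, tt, x, y))
            t = ts[-1] + dt
            t = emit_haulout(t, rng.uniform(1.5, 3.0))
        if t > t_end:
            raise ValueError("track schedule exceeds field temporal coverage; "
                             "shorten trips or extend date_range")
    df = pd.DataFrame(rows, columns=["animal_id", "timestamp", "lon", "lat"])
    if jitter_km > 0:
        jr = np.random.default_rng(np.random.SeedSequence(seed).spawn(n_individuals + 1)[-1])
        brg = jr.uniform(0, 360, len(df))
        dist = np.abs(jr.normal(0, jitter_km, len(df)))
        lon2, lat2 = destination(df["lon"].values, df["lat"].values, brg, dist)
        df["lon"], df["lat"] = lon2, lat2
    df["lc"] = "G"
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def write_tracks_csv(tracks: pd.DataFrame, path) -> None:
    out = tracks.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_tracks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def default_rookery(env: xr.Dataset) -> tuple[float, float]:
    """A sea cell adjacent to the coast, mid-domain in latitude."""
    coast = float(env.attrs["coast_lon"])
    step = float(env["lon"].values[1] - env["lon"].values[0])
    lat_mid = float(env["lat"].values[len(env["lat"]) // 2])
    lon = coast - 1.5 * step
    lon = float(env["lon"].values[np.argmin(np.abs(env["lon"].values - lon))])
    return lon, lat_mid
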