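"""Track regularization, trip segmentation, and space-use summaries.

Raw telemetry is cleaned with an iterative speed filter (in place of a
full state-space location-error model), linearly interpolated to one
position per day at 00:00 UTC, and segmented into foraging trips: maximal
runs of at-sea positions between haul-out states, where a haul-out is any
daily position within a radius of the colony or on land. Each trip splits
into an outgoing and an incoming phase at its apex (the position farthest
from the colony, earliest index on ties).

Also provides great-circle trip metrics, a kernel utilization distribution
with 50%/95% contours, and summaries of the packaged 72-trip reference
table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon
from skimage import measure

from ._geo import great_circle_km

KM_PER_DEG = 111.32

DEFAULT_VMAX_MS = 3.0          # sustained-speed cap for this species
DEFAULT_HAULOUT_RADIUS_KM = 5.0
DEFAULT_GAP_TOL_DAYS = 3.0


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class Trip:
    """A haul-out-to-haul-out at-sea segment of one animal's daily track."""

    trip_id: str
    animal_id: str
    colony: tuple[float, float]
    positions: pd.DataFrame  # columns: date, lon, lat (one row per day)

    @property
    def start_date(self):
        return self.positions["date"].iloc[0]

    @property
    def end_date(self):
        return self.positions["date"].iloc[-1]

    @property
    def n_locations(self) -> int:
        return len(self.positions)


@dataclass
class TripPhase:
    trip_id: str
    phase: str  # "outgoing" | "incoming"
    colony: tuple[float, float]
    positions: pd.DataFrame


@dataclass
class TripMetrics:
    duration_days: int
    max_distance_km: float
    total_distance_km: float


@dataclass
class UtilizationDistribution:
    lon: np.ndarray
    lat: np.ndarray
    density: np.ndarray          # integrates to ~1 over the grid
    bandwidth_km: float
    contours: dict               # level (e.g. 50) -> shapely MultiPolygon
    areas_km2: dict              # level -> area of the contour region


# ---------------------------------------------------------------------------
# Filtering and regularization
# ---------------------------------------------------------------------------

def _implied_speeds_ms(df: pd.DataFrame) -> np.ndarray:
    dt = np.diff(df["timestamp"].astype("int64").to_numpy()) / 1e9
    dist_km = great_circle_km(df["lon"].values[:-1], df["lat"].values[:-1],
                              df["lon"].values[1:], df["lat"].values[1:])
    with np.errstate(divide="ignore"):
        return np.where(dt > 0, dist_km * 1000.0 / np.maximum(dt, 1e-9), np.inf)


def speed_filter(raw: pd.DataFrame, vmax_ms: float = DEFAULT_VMAX_MS) -> pd.DataFrame:
    """Iteratively remove positions implying sustained speed above vmax.

    An interior position is removed when the implied speed to both its
    neighbours exceeds vmax; the last position when its single incoming
    speed does. The first position is always kept. Repeats to convergence.
    """
    if len(raw) < 2:
        return raw.reset_index(drop=True)
    df = raw.sort_values("timestamp").reset_index(drop=True)
    while len(df) >= 2:
        sp = _implied_speeds_ms(df)
        flag = np.zeros(len(df), dtype=bool)
        flag[1:-1] = (sp[:-1] > vmax_ms) & (sp[1:] > vmax_ms)
        if not flag.any():
            # only once no interior spike remains may the trailing point be
            # judged by its single incoming speed
            if sp[-1] > vmax_ms:
                flag[-1] = True
            else:
                break
        df = df.loc[~flag].reset_index(drop=True)
    return df


def regularize_daily(raw: pd.DataFrame, landmask=None,
                     gap_tol_days: float = DEFAULT_GAP_TOL_DAYS) -> pd.DataFrame:
    """Linear interpolation to one position per day at 00:00 UTC.

    Daily epochs whose bracketing observations are more than
    ``gap_tol_days`` apart are omitted; positions falling on land (per the
    ``landmask(lon, lat)`` callable, if given) are removed. Raises if no
    usable daily position remains.
    """
    df = raw.sort_values("timestamp").reset_index(drop=True)
    ts = df["timestamp"]
    t = ts.astype("int64").to_numpy() / 1e9
    first_day = ts.iloc[0].ceil("D")
    last_day = ts.iloc[-1].floor("D")
    if first_day > last_day:
        raise ValueError("track spans less than one daily epoch")
    epochs = pd.date_range(first_day, last_day, freq="D")
    te = epochs.astype("int64").to_numpy() / 1e9
    if epochs.tz is not None:  # store daily dates tz-naive (UTC)
        epochs = epochs.tz_localize(None)
    lon = np.interp(te, t, df["lon"].to_numpy(float))
    lat = np.interp(te, t, df["lat"].to_numpy(float))
    idx = np.searchsorted(t, te)
    prev = np.clip(idx - 1, 0, len(t) - 1)
    nxt = np.clip(idx, 0, len(t) - 1)
    exact = np.isin(te, t)
    gap_days = (t[nxt] - t[prev]) / 86400.0
    ok = exact | (gap_days <= gap_tol_days)
    out = pd.DataFrame({"date": epochs[ok], "lon": lon[ok], "lat": lat[ok]})
    if landmask is not None and len(out):
        on_land = np.asarray(landmask(out["lon"].values, out["lat"].values))
        out = out.loc[~on_land].reset_index(drop=True)
    if out.empty:
        raise ValueError("regularization produced no usable daily positions")
    if "animal_id" in raw.columns:
        out.insert(0, "animal_id", raw["animal_id"].iloc[0])
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Trips and phases
# ---------------------------------------------------------------------------

def segment_trips(daily: pd.DataFrame, colony: tuple[float, float],
                  haulout_radius_km: float = DEFAULT_HAULOUT_RADIUS_KM,
                  landmask=None) -> list[Trip]:
    """Split a daily track into foraging trips between haul-out states.

    A daily position is a haul-out state when within ``haulout_radius_km``
    of the colony or on land. Maximal at-sea runs bounded by haul-outs on
    both sides become trips; runs touching the start or end of the record
    without a bounding haul-out are discarded as incomplete.
    """
    if daily.empty:
        return []
    d = great_circle_km(daily["lon"].values, daily["lat"].values,
                        colony[0], colony[1])
    haul = d <= haulout_radius_km
    if landmask is not None:
        haul |= np.asarray(landmask(daily["lon"].values, daily["lat"].values))
    animal = daily["animal_id"].iloc[0] if "animal_id" in daily.columns else "?"
    trips: list[Trip] = []
    n = len(daily)
    i = 0
    k = 0
    while i < n:
        if haul[i]:
            i += 1
            continue
        j = i
        while j < n and not haul[j]:
            j += 1
        bounded = (i > 0) and (j < n)
        if bounded:
            k += 1
            pos = daily.iloc[i:j][["date", "lon", "lat"]].reset_index(drop=True)
            trips.append(Trip(trip_id=f"{animal}_T{k:02d}", animal_id=animal,
                              colony=colony, positions=pos))
        i = j
    return trips


def split_phases(trip: Trip) -> tuple[TripPhase, TripPhase]:
    """Split a trip at its apex into outgoing and incoming phases.

    The apex (earliest index on ties) belongs to both phases.
    """
    if trip.n_locations < 2:
        raise ValueError("trip must have at least 2 positions")
    d = great_circle_km(trip.positions["lon"].values,
                        trip.positions["lat"].values,
                        trip.colony[0], trip.colony[1])
    apex = int(np.argmax(d))
    out = trip.positions.iloc[:apex + 1].reset_index(drop=True)
    inc = trip.positions.iloc[apex:].reset_index(drop=True)
    return (TripPhase(trip.trip_id, "outgoing", trip.colony, out),
            TripPhase(trip.trip_id, "incoming", trip.colony, inc))


def trip_metrics(trip: Trip) -> TripMetrics:
    """Duration (days at sea), maximum colony distance, and path length."""
    lon = trip.positions["lon"].values
    lat = trip.positions["lat"].values
    dmax = float(np.max(great_circle_km(lon, lat, *trip.colony)))
    steps = great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    return TripMetrics(duration_days=trip.n_locations,
                       max_distance_km=dmax,
                       total_distance_km=float(np.sum(steps)))


def trips_table(trips: list[Trip]) -> pd.DataFrame:
    rows = []
    for tr in trips:
        m = trip_metrics(tr)
        rows.append({"trip_id": tr.trip_id, "animal_id": tr.animal_id,
                     "start_date": tr.start_date, "end_date": tr.end_date,
                     "duration_days": m.duration_days,
                     "max_distance_km": m.max_distance_km,
                     "total_distance_km": m.total_distance_km})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kernel utilization distribution
# ---------------------------------------------------------------------------

def kernel_ud(points: pd.DataFrame, grid_step: float = 0.05,
              levels: tuple[int, ...] = (50, 95),
              pad_bandwidths: float = 3.0) -> UtilizationDistribution:
    """Gaussian kernel UD on a planar equirectangular projection.

    Uses the classical reference bandwidth h = sigma * n^(-1/6) with
    sigma^2 the mean of the coordinate variances, computed in km about the
    points' centroid. Contour levels are the smallest-area regions holding
    the stated probability mass.
    """
    if len(points) < 5:
        raise ValueError("kernel_ud requires at least 5 points")
    lon = points["lon"].to_numpy(float)
    lat = points["lat"].to_numpy(float)
    lat0, lon0 = lat.mean(), lon.mean()
    x = (lon - lon0) * KM_PER_DEG * np.cos(np.radians(lat0))
    y = (lat - lat0) * KM_PER_DEG
    n = len(x)
    sigma = np.sqrt(0.5 * (np.var(x, ddof=1) + np.var(y, ddof=1)))
    if sigma == 0:
        sigma = 1e-6
    h = sigma * n ** (-1.0 / 6.0)

    step_km = grid_step * KM_PER_DEG
    pad = pad_bandwidths * h
    gx = np.arange(x.min() - pad, x.max() + pad + step_km, step_km)
    gy = np.arange(y.min() - pad, y.max() + pad + step_km, step_km)
    dx = gx[None, None, :] - x[:, None, None]
    dy = gy[None, :, None] - y[:, None, None]
    dens = np.exp(-0.5 * (dx * dx + dy * dy) / (h * h)).sum(axis=0)
    dens /= n * 2.0 * np.pi * h * h

    cell = step_km * step_km
    order = np.argsort(dens.ravel())[::-1]
    cum = np.cumsum(dens.ravel()[order]) * cell
    contours = {}
    areas = {}
    for lev in levels:
        target = lev / 100.0
        kidx = int(np.searchsorted(cum, target))
        kidx = min(kidx, len(order) - 1)
        thresh = dens.ravel()[order][kidx]
        padded = np.pad(dens, 1, constant_values=0.0)
        polys = []
        for c in measure.find_contours(padded, thresh):
            iy = c[:, 0] - 1.0
            ix = c[:, 1] - 1.0
            cx = np.interp(ix, np.arange(len(gx)), gx)
            cy = np.interp(iy, np.arange(len(gy)), gy)
            plon = lon0 + cx / (KM_PER_DEG * np.cos(np.radians(lat0)))
            plat = lat0 + cy / KM_PER_DEG
            if len(plon) >= 4:
                p = Polygon(np.column_stack([plon, plat]))
                if p.is_valid and p.area > 0:
                    polys.append(p)
        contours[lev] = MultiPolygon(polys) if polys else MultiPolygon([])
        areas[lev] = float((dens >= thresh).sum()) * cell

    glon = lon0 + gx / (KM_PER_DEG * np.cos(np.radians(lat0)))
    glat = lat0 + gy / KM_PER_DEG
    return UtilizationDistribution(lon=glon, lat=glat, density=dens,
                                   bandwidth_km=float(h), contours=contours,
                                   areas_km2=areas)


def ud_to_geojson(ud: UtilizationDistribution) -> dict:
    """UD contours as a GeoJSON FeatureCollection (one feature per level)."""
    feats = []
    for lev, mp in ud.contours.items():
        feats.append({
            "type": "Feature",
            "properties": {"level_percent": lev, "area_km2": ud.areas_km2[lev],
                           "bandwidth_km": ud.bandwidth_km},
            "geometry": mp.__geo_interface__,
        })
    return {"type": "FeatureCollection", "features": feats}


# ---------------------------------------------------------------------------
# Packaged reference table
# ---------------------------------------------------------------------------

def load_table1() -> pd.DataFrame:
    """Load the packaged 72-trip reference table."""
    with importlib.resources.files("cpforage.data").joinpath(
            "table1_fixture.csv").open() as f:
        return pd.read_csv(f)


def table1_summary(fixture: pd.DataFrame | None = None) -> dict:
    """Count/mean/SD/min/max per numeric column plus tagging-location counts."""
    df = load_table1() if fixture is None else fixture
    required = {"tag_id", "location", "start_date", "end_date",
                "duration_days", "max_distance_km", "total_distance_km"}
    if set(df.columns) != required or len(df) != 72:
        raise ValueError("malformed reference table: expected 72 rows with "
                         f"columns {sorted(required)}")
    out: dict = {"n_trips": int(len(df)),
                 "location_counts": df["location"].value_counts().to_dict()}
    for col in ("duration_days", "max_distance_km", "total_distance_km"):
        s = df[col].astype(float)
        out[col] = {"count": int(s.count()), "mean": float(s.mean()),
                    "sd": float(s.std(ddof=1)), "min": float(s.min()),
                    "max": float(s.max())}
    return out
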