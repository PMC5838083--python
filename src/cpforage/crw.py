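"""Correlated-random-walk null trajectories and the trip-similarity weight.

Pseudoabsences are drawn from a null model of where a central-place
forager could have gone had it moved independently of the environment.
For each trip phase (outgoing, incoming) the observed step-length sequence
and step durations are kept exactly; turning angles are redrawn from a
wrapped normal fitted to the phase's observed angles (circular mean and
SD), with a uniform initial heading. Steps landing on land trigger
resampling of a replacement step length (with replacement from the phase's
step-length pool) plus a fresh angle; persistent failure restarts the
simulation and finally flags it as a land violation.

Each simulation is scored against the observed phase by the dissimilarity
weight

    weight = 2 * (d_track - d_sim) / d_track + |angle_track - angle_sim| / 90

where d is the net (start-to-end) great-circle displacement, the angles
are start-to-end initial bearings, and the bearing difference is wrapped
into [0, 180] degrees. Higher weight = more dissimilar. Simulations in the
upper weight quartile of their trip's set, and land violators, are removed
before one retained simulation is drawn as the trip's pseudoabsence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import circmean, circstd

from ._geo import (bearing_difference_deg, destination, great_circle_km,
                   initial_bearing_deg, wrap_half_open_deg)
from .tracks import Trip, TripPhase, split_phases

MAX_STEP_RETRIES = 100
MAX_RESTARTS = 20


@dataclass
class StepSeries:
    """Observed step geometry of one trip phase."""

    step_lengths_km: np.ndarray      # n steps
    turning_angles_deg: np.ndarray   # n-1 angles in (-180, 180]
    initial_heading_deg: float
    start: tuple[float, float]       # lon, lat
    step_duration_days: np.ndarray
    dates: pd.Series


@dataclass
class NetDisplacement:
    distance_km: float
    bearing_deg: float  # [0, 360); 0 by convention for zero displacement


@dataclass
class CRWSim:
    trip_id: str
    phase: str
    sim_id: int
    positions: pd.DataFrame          # columns: date, lon, lat
    weight: float | None = None
    land_violation: bool = False
    seed_path: tuple = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Observed geometry
# ---------------------------------------------------------------------------

def observed_steps(phase: TripPhase) -> StepSeries:
    """Step lengths, headings and wrapped turning angles of a phase."""
    pos = phase.positions
    if len(pos) < 2:
        raise ValueError("phase must have at least 2 positions")
    lon = pos["lon"].to_numpy(float)
    lat = pos["lat"].to_numpy(float)
    lengths = great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    headings = np.asarray(initial_bearing_deg(lon[:-1], lat[:-1],
                                              lon[1:], lat[1:]), dtype=float)
    turns = wrap_half_open_deg(np.diff(headings))
    dates = pd.to_datetime(pos["date"])
    dt = dates.diff().dropna().dt.total_seconds().to_numpy() / 86400.0
    return StepSeries(step_lengths_km=np.atleast_1d(lengths),
                      turning_angles_deg=np.atleast_1d(turns),
                      initial_heading_deg=float(np.atleast_1d(headings)[0]),
                      start=(float(lon[0]), float(lat[0])),
                      step_duration_days=dt,
                      dates=dates.reset_index(drop=True))


def net_displacement(positions: pd.DataFrame) -> NetDisplacement:
    """Great-circle distance and initial bearing from first to last position."""
    if len(positions) < 2:
        raise ValueError("need at least 2 positions")
    lon = positions["lon"].to_numpy(float)
    lat = positions["lat"].to_numpy(float)
    d = float(great_circle_km(lon[0], lat[0], lon[-1], lat[-1]))
    b = 0.0 if d == 0 else float(initial_bearing_deg(lon[0], lat[0],
                                                     lon[-1], lat[-1]))
    return NetDisplacement(distance_km=d, bearing_deg=b)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _fit_wrapped_normal(turns: np.ndarray) -> tuple[float, float]:
    """Circular mean and circular SD (degrees) of observed turning angles."""
    if turns.size == 0:
        return 0.0, 0.0
    mu = float(circmean(turns, high=180.0, low=-180.0))
    sd = float(circstd(turns, high=180.0, low=-180.0))
    return mu, sd


def _walk(series: StepSeries, landmask, rng) -> tuple[np.ndarray, np.ndarray, bool]:
    """One CRW attempt; returns (lons, lats, ok)."""
    mu, sd = _fit_wrapped_normal(series.turning_angles_deg)
    n_steps = len(series.step_lengths_km)
    lons = np.empty(n_steps + 1)
    lats = np.empty(n_steps + 1)
    lons[0], lats[0] = series.start
    heading = rng.uniform(0.0, 360.0)
    pool = series.step_lengths_km
    for i in range(n_steps):
        length = pool[i]
        if i > 0:
            heading = heading + rng.normal(mu, sd)
        ok = False
        for _retry in range(MAX_STEP_RETRIES + 1):
            lon2, lat2 = destination(lons[i], lats[i], heading % 360.0, length)
            if landmask is None or not landmask(lon2, lat2):
                ok = True
                break
            # rejection: resample a step length from the pool plus a fresh angle
            length = pool[rng.integers(0, len(pool))]
            heading = heading + rng.normal(mu, sd) if i > 0 else rng.uniform(0, 360)
        if not ok:
            return lons, lats, False
        lons[i + 1], lats[i + 1] = lon2, lat2
    return lons, lats, True


def simulate_crw(phase: TripPhase, landmask=None, n_sims: int = 10,
                 seed: int | np.random.SeedSequence = 0) -> list[CRWSim]:
    """Simulate ``n_sims`` CRW null trajectories for one trip phase.

    Each simulation starts at the phase's first observed position and
    preserves the observed step-length sequence exactly unless a land
    rejection forces pool resampling. Deterministic under a fixed seed.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    series = observed_steps(phase)
    if landmask is not None and landmask(*series.start):
        raise ValueError("phase start position lies on land: unsatisfiable mask")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(n_sims)
    sims = []
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        violation = False
        for _attempt in range(MAX_RESTARTS + 1):
            lons, lats, ok = _walk(series, landmask, rng)
            if ok:
                break
        else:
            pass
        if not ok:
            violation = True
        pos = pd.DataFrame({"date": series.dates.values, "lon": lons, "lat": lats})
        sims.append(CRWSim(trip_id=phase.trip_id, phase=phase.phase, sim_id=s,
                           positions=pos, land_violation=violation,
                           seed_path=tuple(child.spawn_key)))
    return sims


# ---------------------------------------------------------------------------
# Weighting and filtering
# ---------------------------------------------------------------------------

def crw_weight(track_nd: NetDisplacement, sim_nd: NetDisplacement,
               scale_whole_sum: bool = False,
               absolute_differences: bool = False) -> float:
    """Dissimilarity weight between an observed and simulated displacement.

    Literal form: 2*(d_track - d_sim)/d_track + dAngle/90 with the bearing
    difference wrapped into [0, 180]. ``scale_whole_sum`` applies the
    leading factor 2 to both terms; ``absolute_differences`` takes the
    distance difference as an absolute value. Defaults follow the literal
    form.
    """
    if track_nd.distance_km <= 0:
        raise ValueError("degenerate trip: zero net displacement")
    ddiff = track_nd.distance_km - sim_nd.distance_km
    if absolute_differences:
        ddiff = abs(ddiff)
    dterm = ddiff / track_nd.distance_km
    aterm = bearing_difference_deg(track_nd.bearing_deg, sim_nd.bearing_deg) / 90.0
    if scale_whole_sum:
        return 2.0 * (dterm + aterm)
    return 2.0 * dterm + aterm


def score_sims(phase: TripPhase, sims: list[CRWSim], **weight_kwargs) -> list[CRWSim]:
    """Attach the dissimilarity weight of each simulation to its phase."""
    track_nd = net_displacement(phase.positions)
    for s in sims:
        s.weight = crw_weight(track_nd, net_displacement(s.positions),
                              **weight_kwargs)
    return sims


def filter_sims(sims: list[CRWSim]) -> list[CRWSim]:
    """Drop land violators, then weights strictly above the 75th percentile.

    The quartile is the linear-interpolation quantile of the trip's own
    (clean) simulation set. Raises if nothing survives.
    """
    clean = [s for s in sims if not s.land_violation]
    if not clean:
        raise ValueError("all simulations removed (land violations); "
                         "increase n_sims")
    if any(s.weight is None for s in clean):
        raise ValueError("simulations must be scored before filtering")
    w = np.array([s.weight for s in clean])
    q75 = float(np.quantile(w, 0.75))
    kept = [s for s in clean if s.weight <= q75]
    if not kept:
        raise ValueError("all simulations removed by the quartile rule")
    return kept


def select_pseudoabsence(retained: list[CRWSim],
                         seed: int | np.random.SeedSequence = 0) -> CRWSim:
    """Uniform seeded selection of one retained simulation."""
    if not retained:
        raise ValueError("no retained simulations to select from")
    rng = np.random.default_rng(seed)
    return retained[int(rng.integers(0, len(retained)))]


# ---------------------------------------------------------------------------
# Trip-level orchestration
# ---------------------------------------------------------------------------

def simulate_trip_nulls(trip: Trip, landmask=None, n_sims: int = 10,
                        seed: int = 0, **weight_kwargs) -> dict[str, list[CRWSim]]:
    """Simulate, score and filter CRWs for both phases of a trip.

    Returns {"outgoing": retained sims, "incoming": retained sims}; a phase
    with fewer than 2 positions yields an empty list.
    """
    ss = np.random.SeedSequence(seed)
    out_ss, in_ss = ss.spawn(2)
    result: dict[str, list[CRWSim]] = {}
    for ph, child in zip(split_phases(trip), (out_ss, in_ss)):
        if len(ph.positions) < 2 or net_displacement(ph.positions).distance_km == 0:
            result[ph.phase] = []
            continue
        sims = simulate_crw(ph, landmask=landmask, n_sims=n_sims, seed=child)
        score_sims(ph, sims, **weight_kwargs)
        result[ph.phase] = filter_sims(sims)
    return result


def null_trip_positions(retained: dict[str, list[CRWSim]],
                        seed: int = 0) -> pd.DataFrame:
    """Select one retained CRW per phase and concatenate into a null trip.

    The duplicated apex date (last outgoing = first incoming) keeps the
    outgoing simulation's position. Returns columns date, lon, lat, sim_id.
    """
    ss = np.random.SeedSequence(seed)
    picks = {}
    for phase, child in zip(("outgoing", "incoming"), ss.spawn(2)):
        if retained.get(phase):
            picks[phase] = select_pseudoabsence(retained[phase], child)
    if not picks:
        raise ValueError("no retained simulations in either phase")
    frames = []
    sim_label = []
    for phase in ("outgoing", "incoming"):
        if phase not in picks:
            continue
        pos = picks[phase].positions.copy()
        if frames:  # drop duplicated apex date
            pos = pos.iloc[1:]
        frames.append(pos)
        sim_label.append(f"{phase[0]}{picks[phase].sim_id}")
    out = pd.concat(frames, ignore_index=True)
    out["sim_id"] = "_".join(sim_label)
    return out


def sims_table(all_sims: dict[str, dict[str, list[CRWSim]]]) -> pd.DataFrame:
    """Long-format table of retained simulations (one row per position)."""
    rows = []
    for trip_id, phases in all_sims.items():
        for phase, sims in phases.items():
            for s in sims:
                for i, r in s.positions.iterrows():
                    rows.append({"trip_id": trip_id, "phase": phase,
                                 "sim_id": s.sim_id, "step_index": i,
                                 "date": r["date"], "lon": r["lon"],
                                 "lat": r["lat"]})
    return pd.DataFrame(rows)


def weights_table(all_sims: dict[str, dict[str, list[CRWSim]]],
                  retained_ids: dict | None = None) -> pd.DataFrame:
    rows = []
    for trip_id, phases in all_sims.items():
        for phase, sims in phases.items():
            for s in sims:
                rows.append({"trip_id": trip_id, "phase": phase,
                             "sim_id": s.sim_id, "weight": s.weight,
                             "land_violation": s.land_violation})
    return pd.DataFrame(rows)
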