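"""Great-circle geometry on a spherical Earth.

All distances in kilometres (Earth radius 6371.0 km), all angles in degrees.
Bearings are compass-style: 0 = north, 90 = east, in [0, 360).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine distance between points, vectorised over array inputs."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial (forward) bearing from point 1 to point 2 in [0, 360).

    Coincident points return 0 by convention.
    """
    lon1r, lat1r, lon2r, lat2r = (np.radians(np.asarray(a, dtype=float))
                                  for a in (lon1, lat1, lon2, lat2))
    dlon = lon2r - lon1r
    y = np.sin(dlon) * np.cos(lat2r)
    x = np.cos(lat1r) * np.sin(lat2r) - np.sin(lat1r) * np.cos(lat2r) * np.cos(dlon)
    brg = np.degrees(np.arctan2(y, x)) % 360.0
    same = (np.asarray(lon1) == np.asarray(lon2)) & (np.asarray(lat1) == np.asarray(lat2))
    return np.where(same, 0.0, brg) if np.ndim(brg) else (0.0 if same else float(brg))


def destination(lon, lat, bearing_deg, distance_km):
    """Forward geodesic: point reached from (lon, lat) on the given bearing."""
    lonr = np.radians(np.asarray(lon, dtype=float))
    latr = np.radians(np.asarray(lat, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(latr) * np.cos(delta) +
                     np.cos(latr) * np.sin(delta) * np.cos(brg))
    lon2 = lonr + np.arctan2(np.sin(brg) * np.sin(delta) * np.cos(latr),
                             np.cos(delta) - np.sin(latr) * np.sin(lat2))
    lon2 = (np.degrees(lon2) + 180.0) % 360.0 - 180.0
    return lon2, np.degrees(lat2)


def wrap_half_open_deg(angle):
    """Wrap an angle difference into (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    out = -((180.0 - a) % 360.0 - 180.0)
    return out if np.ndim(angle) else float(out)


def bearing_difference_deg(b1, b2):
    """Absolute difference of two bearings, wrapped into [0, 180]."""
    d = np.abs(wrap_half_open_deg(np.asarray(b1, dtype=float) - np.asarray(b2, dtype=float)))
    return d if np.ndim(d) else float(d)
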