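"""Great-circle geometry on a spherical Earth.

All stages of the pipeline measure step lengths, headings and turning
angles on the sphere (R = 6371 km).  At the O(100 km) step lengths of
over-water raptor migration the sphere/ellipsoid discrepancy is far below
every other source of error, so no ellipsoidal geodesics are attempted.

Functions accept scalars or numpy arrays and broadcast like numpy ufuncs.
Latitudes/longitudes are degrees; bearings are degrees clockwise from true
north in [0, 360); distances are kilometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GeoPoint:
    """A geographic point; lat in [-90, 90], lon normalized to [-180, 180)."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        lon = ((self.lon + 180.0) % 360.0) - 180.0
        object.__setattr__(self, "lon", float(lon))
        object.__setattr__(self, "lat", float(self.lat))


def gc_distance(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance in km. Symmetric, >= 0."""
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.shape else float(d)


def initial_bearing(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2.

    Degrees clockwise from true north, in [0, 360).  Undefined for
    coincident points: scalar inputs raise ValueError, array inputs
    yield NaN at coincident pairs.
    """
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlam = l2 - l1
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    brg = np.degrees(np.arctan2(y, x)) % 360.0
    coincident = (np.asarray(lat1, dtype=float) == np.asarray(lat2, dtype=float)) & (
        ((np.asarray(lon1, dtype=float) - np.asarray(lon2, dtype=float)) % 360.0) == 0.0
    )
    if brg.shape:
        return np.where(coincident, np.nan, brg)
    if coincident:
        raise ValueError("initial_bearing undefined for coincident points")
    return float(brg)


def destination_point(lat, lon, bearing_deg, distance_km):
    """Point reached by travelling ``distance_km`` along an initial bearing.

    Returns ``(lat, lon)`` with lon in [-180, 180).  Inverse of
    (gc_distance, initial_bearing) to ~1e-6 relative.
    """
    p1 = np.radians(np.asarray(lat, dtype=float))
    l1 = np.radians(np.asarray(lon, dtype=float))
    th = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    sinp2 = np.sin(p1) * np.cos(delta) + np.cos(p1) * np.sin(delta) * np.cos(th)
    p2 = np.arcsin(np.clip(sinp2, -1.0, 1.0))
    l2 = l1 + np.arctan2(
        np.sin(th) * np.sin(delta) * np.cos(p1),
        np.cos(delta) - np.sin(p1) * sinp2,
    )
    lat2 = np.degrees(p2)
    lon2 = (np.degrees(l2) + 180.0) % 360.0 - 180.0
    if np.shape(lat2):
        return lat2, lon2
    return float(lat2), float(lon2)


def turning_angle(h_prev, h_next):
    """Signed heading change ``h_next - h_prev`` wrapped to (-180, 180].

    Positive = clockwise turn.  A reversal maps to +180 by convention.
    """
    d = (np.asarray(h_next, dtype=float) - np.asarray(h_prev, dtype=float)) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)  # %360 keeps exactly 180 positive
    return d if d.shape else float(d)
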