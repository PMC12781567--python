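"""Great-circle geometry and map projection helpers.

Conventions: positions are WGS-84 latitude/longitude in degrees,
bearings are degrees clockwise from true north, distances are km on a
spherical Earth of radius 6371 km.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "initial_bearing",
    "destination_point",
    "laea_project",
    "laea_unproject",
]


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (haversine formula, R = 6371 km)."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((p2 - p1) / 2) ** 2
        + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360)."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dl = l2 - l1
    y = np.sin(dl) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl)
    return np.mod(np.degrees(np.arctan2(y, x)), 360.0)


def destination_point(lat, lon, bearing_deg, dist_km):
    """Point reached from (lat, lon) along a great circle."""
    p1, l1, br = map(np.radians, (lat, lon, bearing_deg))
    d = np.asarray(dist_km, dtype=float) / EARTH_RADIUS_KM
    p2 = np.arcsin(np.sin(p1) * np.cos(d) + np.cos(p1) * np.sin(d) * np.cos(br))
    l2 = l1 + np.arctan2(
        np.sin(br) * np.sin(d) * np.cos(p1), np.cos(d) - np.sin(p1) * np.sin(p2)
    )
    lat2 = np.degrees(p2)
    lon2 = (np.degrees(l2) + 180.0) % 360.0 - 180.0
    return lat2, lon2


def laea_project(lat, lon, lat0, lon0):
    """Lambert azimuthal equal-area projection centred at (lat0, lon0), km.

    Equal-area by construction, distance-true near the centre; used for
    foraging-range kernel density estimates so that density mass is not
    distorted by latitude.
    """
    p, l = np.radians(lat), np.radians(lon)
    p0, l0 = np.radians(lat0), np.radians(lon0)
    dl = l - l0
    denom = 1.0 + np.sin(p0) * np.sin(p) + np.cos(p0) * np.cos(p) * np.cos(dl)
    k = np.sqrt(2.0 / np.maximum(denom, 1e-12))
    x = EARTH_RADIUS_KM * k * np.cos(p) * np.sin(dl)
    y = EARTH_RADIUS_KM * k * (
        np.cos(p0) * np.sin(p) - np.sin(p0) * np.cos(p) * np.cos(dl)
    )
    return x, y


def laea_unproject(x, y, lat0, lon0):
    """Inverse of :func:`laea_project`."""
    x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
    y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
    p0, l0 = np.radians(lat0), np.radians(lon0)
    rho = np.hypot(x, y)
    c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(
            rho < 1e-12,
            p0,
            np.arcsin(np.cos(c) * np.sin(p0) + y * np.sin(c) * np.cos(p0) / np.where(rho == 0, 1, rho)),
        )
        l = l0 + np.arctan2(
            x * np.sin(c),
            rho * np.cos(p0) * np.cos(c) - y * np.sin(p0) * np.sin(c),
        )
    lon = (np.degrees(l) + 180.0) % 360.0 - 180.0
    return np.degrees(p), lon
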