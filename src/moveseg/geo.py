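"""Spherical geometry: local planar projection, geodesic distances, bearings.

The study area (southern Tyrrhenian Sea, ~10^3 km across) is small enough
that a spherical azimuthal equidistant projection centred on the capture
area introduces distortion far below Argos location error, so all Kalman
and kernel-density algebra is done in this planar km frame and longitudes/
latitudes are recovered by the exact inverse projection.
"""
from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088

#: default projection centre: capture area around Filicudi, Aeolian Islands
STUDY_CENTER_LON = 14.7
STUDY_CENTER_LAT = 38.5


def project_aeqd(lon, lat, lon0: float = STUDY_CENTER_LON, lat0: float = STUDY_CENTER_LAT):
    """Forward azimuthal equidistant projection to planar km.

    Returns ``(x, y)`` in km east/north of the centre ``(lon0, lat0)``.
    Exact on the sphere: the straight-line distance from the origin equals
    the great-circle distance, and azimuths at the origin are preserved.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    dlam = lam - lam0
    cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
    cosc = np.clip(cosc, -1.0, 1.0)
    c = np.arccos(cosc)
    # k = c / sin(c) -> 1 as c -> 0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
    y = EARTH_RADIUS_KM * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam))
    return x, y


def unproject_aeqd(x, y, lon0: float = STUDY_CENTER_LON, lat0: float = STUDY_CENTER_LAT):
    """Inverse azimuthal equidistant projection: planar km back to lon/lat degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    rho = np.hypot(x, y)
    c = rho / EARTH_RADIUS_KM
    sinc, cosc = np.sin(c), np.cos(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(rho > 1e-12, sinc / np.where(rho > 1e-12, rho, 1.0), 0.0)
    phi = np.arcsin(np.clip(cosc * np.sin(phi0) + y * frac * np.cos(phi0), -1.0, 1.0))
    lam = lam0 + np.arctan2(x * sinc, rho * np.cos(phi0) * cosc - y * np.sin(phi0) * sinc)
    lam = np.where(rho > 1e-12, lam, lam0)
    phi = np.where(rho > 1e-12, phi, phi0)
    lon = np.degrees(lam)
    # keep longitudes in [-180, 180); the study area never crosses the antimeridian
    lon = (lon + 180.0) % 360.0 - 180.0
    return lon, np.degrees(phi)


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km (haversine formula)."""
    lon1, lat1 = np.radians(np.asarray(lon1, float)), np.radians(np.asarray(lat1, float))
    lon2, lat2 = np.radians(np.asarray(lon2, float)), np.radians(np.asarray(lat2, float))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def vincenty_sphere_km(lon1, lat1, lon2, lat2):
    """Great-circle distance via the atan2 (Vincenty-type) formula.

    Numerically independent route from :func:`haversine_km`; used as a
    cross-check oracle in tests.
    """
    lon1, lat1 = np.radians(np.asarray(lon1, float)), np.radians(np.asarray(lat1, float))
    lon2, lat2 = np.radians(np.asarray(lon2, float)), np.radians(np.asarray(lat2, float))
    dlon = lon2 - lon1
    num = np.hypot(
        np.cos(lat2) * np.sin(dlon),
        np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon),
    )
    den = np.sin(lat1) * np.sin(lat2) + np.cos(lat1) * np.cos(lat2) * np.cos(dlon)
    return EARTH_RADIUS_KM * np.arctan2(num, den)


def initial_bearing_rad(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2, radians clockwise from north."""
    lon1, lat1 = np.radians(np.asarray(lon1, float)), np.radians(np.asarray(lat1, float))
    lon2, lat2 = np.radians(np.asarray(lon2, float)), np.radians(np.asarray(lat2, float))
    dlon = lon2 - lon1
    x = np.sin(dlon) * np.cos(lat2)
    y = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(x, y)


def wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return out
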