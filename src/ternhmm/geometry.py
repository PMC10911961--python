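"""Great-circle geometry primitives for 1 Hz track processing.

All distances are in kilometres on a sphere of radius ``EARTH_RADIUS_KM``;
bearings are in radians measured clockwise from due north in [0, 2*pi);
turning angles are signed, counter-clockwise positive, wrapped to (-pi, pi].
The sub-100-km scales of boat-based visual tracking make the spherical
approximation error negligible, so no map projection is used.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "great_circle_km",
    "initial_bearing",
    "destination_point",
    "wrap_angle",
]


class UndefinedBearingError(ValueError):
    """Raised when an initial bearing is requested between coincident points."""


def wrap_angle(angle):
    """Wrap an angle (radians) to the half-open interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(angle, dtype=float), 2.0 * np.pi)


def great_circle_km(lon1, lat1, lon2, lat2, radius=EARTH_RADIUS_KM):
    """Haversine distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays; symmetric and non-negative.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards rounding for antipodal / coincident points
    return 2.0 * radius * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def initial_bearing(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2.

    Returns radians in [0, 2*pi), 0 = due north, clockwise positive.

    Raises
    ------
    UndefinedBearingError
        If any requested pair of points is coincident.
    """
    lon1r, lat1r, lon2r, lat2r = (np.radians(np.asarray(x, dtype=float))
                                  for x in (lon1, lat1, lon2, lat2))
    dlon = lon2r - lon1r
    y = np.sin(dlon) * np.cos(lat2r)
    x = np.cos(lat1r) * np.sin(lat2r) - np.sin(lat1r) * np.cos(lat2r) * np.cos(dlon)
    if np.any((np.abs(y) < 1e-300) & (np.abs(x) < 1e-300)):
        raise UndefinedBearingError("initial bearing is undefined for coincident points")
    return np.mod(np.arctan2(y, x), 2.0 * np.pi)


def destination_point(lon, lat, bearing, distance_km, radius=EARTH_RADIUS_KM):
    """Point reached from (lon, lat) travelling ``distance_km`` along ``bearing``.

    Standard great-circle destination formula:

        lat2 = arcsin(sin lat * cos(d/R) + cos lat * sin(d/R) * cos b)
        lon2 = lon + atan2(sin b * sin(d/R) * cos lat,
                           cos(d/R) - sin lat * sin lat2)

    Longitude of the result is normalised to [-180, 180].  Inverse of
    (:func:`initial_bearing`, :func:`great_circle_km`) for sub-antipodal
    distances; used to reconstruct an animal's position from an observer
    fix plus a recorded bearing and range.
    """
    lonr = np.radians(np.asarray(lon, dtype=float))
    latr = np.radians(np.asarray(lat, dtype=float))
    bearing = np.asarray(bearing, dtype=float)
    frac = np.asarray(distance_km, dtype=float) / radius
    lat2 = np.arcsin(np.sin(latr) * np.cos(frac)
                     + np.cos(latr) * np.sin(frac) * np.cos(bearing))
    y = np.sin(bearing) * np.sin(frac) * np.cos(latr)
    x = np.cos(frac) - np.sin(latr) * np.sin(lat2)
    lon2 = lonr + np.arctan2(y, x)
    lon2_deg = np.degrees(lon2)
    lon2_deg = np.mod(lon2_deg + 180.0, 360.0) - 180.0
    # keep exact +180 rather than -180 after the mod
    lon2_deg = np.where(np.isclose(np.degrees(lon2), 180.0), 180.0, lon2_deg)
    return lon2_deg, np.degrees(lat2)
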