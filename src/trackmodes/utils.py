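"""Shared geometry helpers: angle wrapping, great-circle distance and bearing."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def wrap_to_pi(angle):
    """Wrap angles (radians) to the interval (-pi, pi]."""
    a = np.asarray(angle, dtype=float)
    wrapped = np.mod(a + np.pi, 2.0 * np.pi) - np.pi
    # mod maps the upper endpoint to -pi; the convention here is (-pi, pi]
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def initial_bearing_rad(lon1, lat1, lon2, lat2):
    """Forward azimuth (radians, clockwise from north) at the start point,
    wrapped to (-pi, pi]."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return wrap_to_pi(np.arctan2(y, x))
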