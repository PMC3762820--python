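"""Great-circle geometry helpers shared by the loaders and spatial statistics."""

from __future__ import annotations

import numpy as np

#: Mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_haversine_km(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Symmetric matrix of great-circle distances (km) with zero diagonal."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    d = haversine_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])
    np.fill_diagonal(d, 0.0)
    return d


def polygon_area_km2(lons: np.ndarray, lats: np.ndarray) -> float:
    """Area of a lon/lat ring in km² via an equal-area local projection.

    Projects to a plane scaled by cos(mean latitude) before applying the
    shoelace formula; accurate to well under 0.1% for town-sized polygons.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    lat0 = np.radians(lats.mean())
    km_per_deg = np.pi * EARTH_RADIUS_KM / 180.0
    x = lons * km_per_deg * np.cos(lat0)
    y = lats * km_per_deg
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
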