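"""Great-circle geometry on the WGS84 mean sphere.

All distances in this package are haversine kilometres on a sphere of
radius 6371.0088 km (the IUGG mean Earth radius); no Euclidean-degree
distances appear in any output.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance between points given in decimal degrees.

    Accepts scalars or broadcastable arrays; returns kilometres.
    """
    lon1, lat1, lon2, lat2 = (np.asarray(a, dtype=float) for a in (lon1, lat1, lon2, lat2))
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude outside [-90, 90]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def pairwise_haversine_km(lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Symmetric n x n great-circle distance matrix in km."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


def destination_point(lon: float, lat: float, bearing_deg: float, distance_km: float):
    """Point reached travelling ``distance_km`` along ``bearing_deg`` on the sphere."""
    if abs(lat) > 90:
        raise ValueError("latitude outside [-90, 90]")
    delta = distance_km / EARTH_RADIUS_KM
    theta = np.radians(bearing_deg)
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    lon2 = (np.degrees(lam2) + 540.0) % 360.0 - 180.0
    return float(lon2), float(np.degrees(phi2))
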