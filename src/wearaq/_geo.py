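"""Small geodesy helpers (haversine distance, local planar projection)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between WGS84 points (vectorized)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def local_xy_m(lon, lat, origin_lon, origin_lat):
    """Equirectangular projection to metres around a local origin.

    Adequate at city scale (error << 100 m cells at mid latitudes).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    kx = np.cos(np.radians(origin_lat)) * EARTH_RADIUS_KM * 1000.0
    ky = EARTH_RADIUS_KM * 1000.0
    x = np.radians(lon - origin_lon) * kx
    y = np.radians(lat - origin_lat) * ky
    return x, y


def offset_lonlat(origin_lon, origin_lat, dx_m, dy_m):
    """Inverse of :func:`local_xy_m`: displace an origin by metres east/north."""
    kx = np.cos(np.radians(origin_lat)) * EARTH_RADIUS_KM * 1000.0
    ky = EARTH_RADIUS_KM * 1000.0
    lon = origin_lon + np.degrees(np.asarray(dx_m, dtype=float) / kx)
    lat = origin_lat + np.degrees(np.asarray(dy_m, dtype=float) / ky)
    return lon, lat
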