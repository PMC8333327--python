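"""Great-circle geometry: haversine distances and distance to a coastline.

Distance to coast is the minimum haversine distance from a station to the
vertices of a supplied coastline polyline (a vertex list stands in for a
gridded 0 m isobath).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km between points in decimal degrees.

    Broadcasts over array inputs. Symmetric; zero iff the points coincide
    (modulo 360 degrees of longitude).
    """
    arrs = [np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2)]
    if any(not np.all(np.isfinite(a)) for a in arrs):
        raise ValueError("coordinates must be finite")
    la1, lo1, la2, lo2 = (np.radians(a) for a in arrs)
    dlat = la2 - la1
    dlon = lo2 - lo1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    if d.ndim == 0:
        return float(d)
    return d


def distance_to_coast(lat, lon, coastline: np.ndarray) -> float:
    """Shortest haversine distance (km) from a station to coastline vertices.

    Parameters
    ----------
    coastline
        Array of shape (m, 2) with (lat, lon) vertices, m >= 1.
    """
    coast = np.asarray(coastline, dtype=float)
    if coast.size == 0:
        raise ValueError("coastline must be non-empty")
    coast = coast.reshape(-1, 2)
    d = haversine_km(lat, lon, coast[:, 0], coast[:, 1])
    return float(np.min(d))


def synthetic_coastline(n_vertices: int = 60) -> np.ndarray:
    """A fixed synthetic archipelago standing in for the 0 m isobath.

    Island vertices are scattered uniformly per unit *area* (latitude drawn
    through an arcsine transform) over the virtual basin, so distance to
    the nearest vertex is patchy everywhere rather than a deterministic
    function of latitude -- a purely meridional coast would make distance
    to coast collinear with temperature through the poleward shrinkage of
    longitude degrees.
    """
    rng = np.random.default_rng(987654321)      # fixed geography
    s = rng.uniform(np.sin(np.radians(-70.0)), np.sin(np.radians(85.0)),
                    n_vertices)
    lat = np.degrees(np.arcsin(s))
    lon = rng.uniform(-70.0, 30.0, n_vertices)
    return np.column_stack([lat, lon])
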