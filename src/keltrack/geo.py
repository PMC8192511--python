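"""Great-circle geometry on the spherical Earth (R = 6371.0 km).

All angles are degrees; longitudes live in [-180, 180). Distances are the
"straight line" migration distances of the analysis: great-circle arcs, not
rhumb lines.
"""

from __future__ import annotations

import numpy as np

from keltrack.errors import ValidationError

EARTH_RADIUS_KM = 6371.0


def wrap_lon(lon):
    """Wrap longitude(s) into [-180, 180)."""
    return (np.asarray(lon) + 180.0) % 360.0 - 180.0


def validate_latlon(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValidationError("non-finite coordinate")
    if np.any(lat < -90.0) or np.any(lat > 90.0):
        raise ValidationError("latitude outside [-90, 90]")
    if np.any(lon < -180.0) or np.any(lon >= 180.0):
        raise ValidationError("longitude outside [-180, 180)")


def great_circle_km(lat1, lon1, lat2, lon2):
    """Haversine distance in km; accepts scalars or broadcastable arrays."""
    for v in (lat1, lat2):
        if np.any(np.abs(np.asarray(v, dtype=float)) > 90.0):
            raise ValidationError("latitude outside [-90, 90]")
    p1, l1, p2, l2 = (np.radians(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, degrees clockwise from north."""
    p1, l1, p2, l2 = (np.radians(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2))
    dlam = l2 - l1
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    return np.degrees(np.arctan2(y, x)) % 360.0


def destination_point(lat, lon, bearing_deg, distance_km):
    """Point reached travelling ``distance_km`` along ``bearing_deg`` on the great circle."""
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    p1 = np.radians(np.asarray(lat, dtype=float))
    l1 = np.radians(np.asarray(lon, dtype=float))
    p2 = np.arcsin(np.sin(p1) * np.cos(delta) + np.cos(p1) * np.sin(delta) * np.cos(theta))
    l2 = l1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(p1),
        np.cos(delta) - np.sin(p1) * np.sin(p2),
    )
    return np.degrees(p2), wrap_lon(np.degrees(l2))


def latlon_to_unit_vectors(lat, lon):
    """(..., 3) unit vectors on the sphere for mean-direction computations."""
    p = np.radians(np.asarray(lat, dtype=float))
    l = np.radians(np.asarray(lon, dtype=float))
    return np.stack([np.cos(p) * np.cos(l), np.cos(p) * np.sin(l), np.sin(p)], axis=-1)


def unit_vectors_to_latlon(vec):
    """Inverse of :func:`latlon_to_unit_vectors`; input need not be normalized."""
    vec = np.asarray(vec, dtype=float)
    norm = np.linalg.norm(vec, axis=-1, keepdims=True)
    v = vec / np.where(norm == 0.0, 1.0, norm)
    lat = np.degrees(np.arcsin(np.clip(v[..., 2], -1.0, 1.0)))
    lon = wrap_lon(np.degrees(np.arctan2(v[..., 1], v[..., 0])))
    return lat, lon
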