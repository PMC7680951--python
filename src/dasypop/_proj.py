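"""Minimal transverse-Mercator (UTM) forward projection.

Used only to compute polygon areas and metric distances for data in
geographic (longitude/latitude, WGS 84) coordinates.  Synthetic data uses a
planar pseudo-projection with metric coordinates and bypasses this entirely.

Implements the standard Krueger series expansion (order n^4) on the WGS 84
ellipsoid; accurate to well under a metre within a UTM zone, which is far
below the tolerance of any area statistic computed here.
"""

from __future__ import annotations

import math

# WGS 84
_A = 6378137.0
_F = 1.0 / 298.257223563
_K0 = 0.9996
_E2 = _F * (2.0 - _F)

PLANAR_CRS_PREFIX = "planar"
GEOGRAPHIC_CRS_IDS = {"EPSG:4326", "WGS84", "CRS84"}


def is_planar(crs_id: str) -> bool:
    """True if coordinates of this CRS are already in metres."""
    return str(crs_id).lower().startswith(PLANAR_CRS_PREFIX)


def utm_zone_of(lon: float) -> int:
    """1-based UTM zone number containing longitude ``lon``."""
    return int((lon + 180.0) // 6.0) % 60 + 1


def utm_central_meridian(zone: int) -> float:
    return -183.0 + 6.0 * zone


def utm_forward(lon: float, lat: float, zone: int) -> tuple[float, float]:
    """Project geographic coordinates (degrees) to UTM easting/northing (m)."""
    lam0 = math.radians(utm_central_meridian(zone))
    lam = math.radians(lon) - lam0
    phi = math.radians(lat)

    # conformal latitude
    e = math.sqrt(_E2)
    sphi = math.sin(phi)
    t = math.sinh(
        math.atanh(sphi) - e * math.atanh(e * sphi)
    )
    xi_p = math.atan2(t, math.cos(lam))
    eta_p = math.asinh(math.sin(lam) / math.hypot(t, math.cos(lam)))

    n = _F / (2.0 - _F)
    n2, n3, n4 = n * n, n ** 3, n ** 4
    a_cap = _A / (1.0 + n) * (1.0 + n2 / 4.0 + n4 / 64.0)
    alpha = (
        n / 2.0 - 2.0 * n2 / 3.0 + 5.0 * n3 / 16.0 + 41.0 * n4 / 180.0,
        13.0 * n2 / 48.0 - 3.0 * n3 / 5.0 + 557.0 * n4 / 1440.0,
        61.0 * n3 / 240.0 - 103.0 * n4 / 140.0,
        49561.0 * n4 / 161280.0,
    )
    xi = xi_p
    eta = eta_p
    for j, a_j in enumerate(alpha, start=1):
        xi += a_j * math.sin(2.0 * j * xi_p) * math.cosh(2.0 * j * eta_p)
        eta += a_j * math.cos(2.0 * j * xi_p) * math.sinh(2.0 * j * eta_p)

    easting = 500000.0 + _K0 * a_cap * eta
    northing = _K0 * a_cap * xi
    if lat < 0:
        northing += 10000000.0
    return easting, northing


def project_ring(coords, zone: int):
    """Project a sequence of (lon, lat) pairs to UTM metres."""
    return [utm_forward(x, y, zone) for x, y in coords]
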