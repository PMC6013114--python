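"""WGS-84 <-> UTM transverse-Mercator projection.

Forward and inverse transverse Mercator on the WGS-84 ellipsoid using
the Krüger series in the third flattening n, truncated at n^4 (errors
well below a millimetre inside a UTM zone), with the standard UTM
parameters: scale 0.9996 at the central meridian, 500 km false easting,
10,000 km false northing in the southern hemisphere.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

__all__ = ["utm_forward", "utm_inverse", "project_to_planar", "utm_central_meridian"]

_A_WGS84 = 6378137.0
_F_WGS84 = 1.0 / 298.257223563
_K0 = 0.9996
_FALSE_EASTING = 500000.0
_FALSE_NORTHING_SOUTH = 10000000.0

_N = _F_WGS84 / (2.0 - _F_WGS84)
# rectifying radius
_A_RECT = _A_WGS84 / (1.0 + _N) * (1.0 + _N**2 / 4.0 + _N**4 / 64.0)
_E = math.sqrt(_F_WGS84 * (2.0 - _F_WGS84))  # first eccentricity

# Krüger series coefficients to n^4
_ALPHA = (
    _N / 2.0 - 2.0 * _N**2 / 3.0 + 5.0 * _N**3 / 16.0 + 41.0 * _N**4 / 180.0,
    13.0 * _N**2 / 48.0 - 3.0 * _N**3 / 5.0 + 557.0 * _N**4 / 1440.0,
    61.0 * _N**3 / 240.0 - 103.0 * _N**4 / 140.0,
    49561.0 * _N**4 / 161280.0,
)
_BETA = (
    _N / 2.0 - 2.0 * _N**2 / 3.0 + 37.0 * _N**3 / 96.0 - _N**4 / 360.0,
    _N**2 / 48.0 + _N**3 / 15.0 - 437.0 * _N**4 / 1440.0,
    17.0 * _N**3 / 480.0 - 37.0 * _N**4 / 840.0,
    4397.0 * _N**4 / 161280.0,
)


def utm_central_meridian(zone: int) -> float:
    """Central meridian (degrees) of a UTM zone (1..60)."""
    if not 1 <= zone <= 60:
        raise ValueError(f"UTM zone must be 1..60, got {zone}")
    return -183.0 + 6.0 * zone


def utm_forward(lon, lat, zone: int = 15, north: bool = True):
    """Project lon/lat (degrees, WGS-84) to UTM easting/northing (metres).

    Points more than ~5 degrees of longitude from the central meridian are
    outside the zone's validity; they are projected anyway with a warning.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lam0 = math.radians(utm_central_meridian(zone))
    dlon = np.radians(lon) - lam0
    dlon = np.arctan2(np.sin(dlon), np.cos(dlon))  # wrap to (-pi, pi]
    if np.any(np.abs(np.degrees(dlon)) > 5.0):
        warnings.warn(
            f"points beyond +/-5 deg of zone {zone} central meridian; distortion grows",
            stacklevel=2,
        )
    phi = np.radians(lat)

    t = np.sinh(
        np.arctanh(np.sin(phi)) - _E * np.arctanh(_E * np.sin(phi))
    )
    xi_p = np.arctan2(t, np.cos(dlon))
    eta_p = np.arcsinh(np.sin(dlon) / np.hypot(t, np.cos(dlon)))

    xi = xi_p.copy()
    eta = eta_p.copy()
    for j, a in enumerate(_ALPHA, start=1):
        xi = xi + a * np.sin(2 * j * xi_p) * np.cosh(2 * j * eta_p)
        eta = eta + a * np.cos(2 * j * xi_p) * np.sinh(2 * j * eta_p)

    easting = _FALSE_EASTING + _K0 * _A_RECT * eta
    northing = _K0 * _A_RECT * xi
    if not north:
        northing = northing + _FALSE_NORTHING_SOUTH
    return easting, northing


def utm_inverse(easting, northing, zone: int = 15, north: bool = True):
    """Inverse of :func:`utm_forward`; returns (lon, lat) in degrees."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    if not north:
        northing = northing - _FALSE_NORTHING_SOUTH
    xi = northing / (_K0 * _A_RECT)
    eta = (easting - _FALSE_EASTING) / (_K0 * _A_RECT)

    xi_p = xi.copy()
    eta_p = eta.copy()
    for j, b in enumerate(_BETA, start=1):
        xi_p = xi_p - b * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_p = eta_p - b * np.cos(2 * j * xi) * np.sinh(2 * j * eta)

    dlon = np.arctan2(np.sinh(eta_p), np.cos(xi_p))
    chi = np.arcsin(np.sin(xi_p) / np.cosh(eta_p))  # conformal latitude

    # invert the conformal latitude by fixed point on sin(phi)
    phi = chi.copy()
    for _ in range(12):
        s = np.sin(phi)
        phi = np.arcsin(np.tanh(np.arctanh(np.sin(chi)) + _E * np.arctanh(_E * s)))

    lon = np.degrees(dlon + math.radians(utm_central_meridian(zone)))
    lon = (lon + 180.0) % 360.0 - 180.0
    lat = np.degrees(phi)
    return lon, lat


def project_to_planar(points, zone: int = 15, north: bool = True) -> np.ndarray:
    """Project an (n, 2) array of lon/lat to planar UTM metres.

    Convenience wrapper used by the hotspot pipeline; synthetic studies
    that are already planar bypass this entirely.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    e, n = utm_forward(pts[:, 0], pts[:, 1], zone=zone, north=north)
    return np.column_stack([e, n])
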