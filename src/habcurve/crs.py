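"""Minimal WGS84 <-> UTM transverse-Mercator transform.

Only the UTM projected systems (EPSG:326xx north / 327xx south) are supported;
all toolkit distances are metric, so geographic inputs (GPX) must be projected
before any geometry is computed. The implementation follows the standard
Krüger series truncated at order six, accurate to well under a millimetre
within a UTM zone — sufficient for 10 m imagery.
"""

from __future__ import annotations

import math
import re

import numpy as np

_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_K0 = 0.9996
_FALSE_EASTING = 500000.0
_FALSE_NORTHING_SOUTH = 10000000.0

_N = _WGS84_F / (2.0 - _WGS84_F)
# meridian-arc scale factor
_A_CAP = _WGS84_A / (1.0 + _N) * (1.0 + _N**2 / 4.0 + _N**4 / 64.0 + _N**6 / 256.0)

# Krüger alpha/beta series coefficients (order 6)
_ALPHA = (
    _N / 2 - 2 * _N**2 / 3 + 5 * _N**3 / 16 + 41 * _N**4 / 180
    - 127 * _N**5 / 288 + 7891 * _N**6 / 37800,
    13 * _N**2 / 48 - 3 * _N**3 / 5 + 557 * _N**4 / 1440 + 281 * _N**5 / 630
    - 1983433 * _N**6 / 1935360,
    61 * _N**3 / 240 - 103 * _N**4 / 140 + 15061 * _N**5 / 26880
    + 167603 * _N**6 / 181440,
    49561 * _N**4 / 161280 - 179 * _N**5 / 168 + 6601661 * _N**6 / 7257600,
    34729 * _N**5 / 80640 - 3418889 * _N**6 / 1995840,
    212378941 * _N**6 / 319334400,
)
_BETA = (
    _N / 2 - 2 * _N**2 / 3 + 37 * _N**3 / 96 - _N**4 / 360 - 81 * _N**5 / 512
    + 96199 * _N**6 / 604800,
    _N**2 / 48 + _N**3 / 15 - 437 * _N**4 / 1440 + 46 * _N**5 / 105
    - 1118711 * _N**6 / 3870720,
    17 * _N**3 / 480 - 37 * _N**4 / 840 - 209 * _N**5 / 4480
    + 5569 * _N**6 / 90720,
    4397 * _N**4 / 161280 - 11 * _N**5 / 504 - 830251 * _N**6 / 7257600,
    4583 * _N**5 / 161280 - 108847 * _N**6 / 3991680,
    20648693 * _N**6 / 638668800,
)

_UTM_RE = re.compile(r"^EPSG:(32[67])(\d{2})$", re.IGNORECASE)


class UnsupportedCrsError(ValueError):
    """Raised when a CRS id is not a UTM EPSG code."""


def parse_utm_epsg(crs_id: str) -> tuple[int, bool]:
    """Return (zone, is_north) for an 'EPSG:326xx'/'EPSG:327xx' id."""
    m = _UTM_RE.match(crs_id.strip())
    if not m:
        raise UnsupportedCrsError(
            f"only UTM EPSG:326xx/327xx codes are supported, got {crs_id!r}"
        )
    zone = int(m.group(2))
    if not 1 <= zone <= 60:
        raise UnsupportedCrsError(f"UTM zone out of range in {crs_id!r}")
    return zone, m.group(1) == "326"


def _central_meridian(zone: int) -> float:
    return math.radians(-183.0 + 6.0 * zone)


def lonlat_to_utm(lon, lat, crs_id: str):
    """Forward transverse Mercator: degrees -> (easting, northing) in meters."""
    zone, north = parse_utm_epsg(crs_id)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    phi = np.radians(lat)
    lam = np.radians(lon) - _central_meridian(zone)

    e2 = _WGS84_F * (2.0 - _WGS84_F)
    # conformal latitude
    t = np.sinh(
        np.arctanh(np.sin(phi))
        - math.sqrt(e2) * np.arctanh(math.sqrt(e2) * np.sin(phi))
    )
    xi = np.arctan2(t, np.cos(lam))
    eta = np.arcsinh(np.sin(lam) / np.hypot(t, np.cos(lam)))

    x = eta.copy()
    y = xi.copy()
    for j, (a,) in enumerate(zip(_ALPHA)):
        k = 2 * (j + 1)
        x = x + a * np.cos(k * xi) * np.sinh(k * eta)
        y = y + a * np.sin(k * xi) * np.cosh(k * eta)

    easting = _FALSE_EASTING + _K0 * _A_CAP * x
    northing = _K0 * _A_CAP * y
    if not north:
        northing = northing + _FALSE_NORTHING_SOUTH
    return easting, northing


def utm_to_lonlat(easting, northing, crs_id: str):
    """Inverse transverse Mercator: meters -> (lon, lat) in degrees."""
    zone, north = parse_utm_epsg(crs_id)
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    if not north:
        northing = northing - _FALSE_NORTHING_SOUTH

    x = (easting - _FALSE_EASTING) / (_K0 * _A_CAP)
    y = northing / (_K0 * _A_CAP)

    xi = y.copy()
    eta = x.copy()
    for j, (b,) in enumerate(zip(_BETA)):
        k = 2 * (j + 1)
        xi = xi - b * np.sin(k * y) * np.cosh(k * x)
        eta = eta - b * np.cos(k * y) * np.sinh(k * x)

    chi = np.arcsin(np.sin(xi) / np.cosh(eta))
    e2 = _WGS84_F * (2.0 - _WGS84_F)
    e = math.sqrt(e2)
    # fixed-point recovery of geodetic from conformal latitude
    phi = chi.copy()
    t_chi = np.arctanh(np.sin(chi))
    for _ in range(8):
        phi = np.arcsin(np.tanh(t_chi + e * np.arctanh(e * np.sin(phi))))
    lam = np.arctan2(np.sinh(eta), np.cos(xi))
    lon = np.degrees(lam + _central_meridian(zone))
    lat = np.degrees(phi)
    return lon, lat
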