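"""Geodesic distance on the WGS-84 ellipsoid (Vincenty inverse formula)."""

from __future__ import annotations

import math

WGS84_A = 6378137.0  # semi-major axis, m
WGS84_F = 1.0 / 298.257223563  # flattening
WGS84_B = WGS84_A * (1.0 - WGS84_F)


def vincenty_distance(
    lat1: float, lon1: float, lat2: float, lon2: float,
    tol: float = 1e-12, max_iter: int = 200,
) -> float:
    """Distance in metres between two (lat, lon) points in decimal degrees.

    Iterative Vincenty inverse solution; falls back to one extra bisection
    step never being needed for the sub-100-km scales used here (the formula
    can fail to converge only for nearly antipodal points, which raises).
    """
    if (lat1, lon1) == (lat2, lon2):
        return 0.0
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - WGS84_F) * math.tan(phi1))
    U2 = math.atan((1 - WGS84_F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.sqrt(
            (cosU2 * sin_lam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2
        )
        if sin_sigma == 0.0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        cos_2sigma_m = 0.0 if cos2_alpha == 0 else cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha
        C = WGS84_F / 16.0 * cos2_alpha * (4 + WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * WGS84_F * sin_alpha * (
            sigma
            + C * sin_sigma * (cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    else:
        raise ValueError("Vincenty did not converge (nearly antipodal points?)")

    u2 = cos2_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos_2sigma_m
            + B
            / 4
            * (
                cos_sigma * (-1 + 2 * cos_2sigma_m**2)
                - B
                / 6
                * cos_2sigma_m
                * (-3 + 4 * sin_sigma**2)
                * (-3 + 4 * cos_2sigma_m**2)
            )
        )
    )
    return WGS84_B * A * (sigma - delta_sigma)


def point_at_distance_north(
    lat: float, lon: float, distance_m: float, tol_m: float = 0.01
) -> tuple[float, float]:
    """Point due north of (lat, lon) at a given geodesic distance.

    Solved by bisection on latitude against the Vincenty distance; adequate
    for placing synthetic sampling sites tens of kilometres apart.
    """
    if distance_m == 0:
        return lat, lon
    lo, hi = lat, min(lat + distance_m / 100_000.0 + 1.0, 89.9)
    while vincenty_distance(lat, lon, hi, lon) < distance_m:
        hi = min(hi + 1.0, 89.9)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        d = vincenty_distance(lat, lon, mid, lon)
        if abs(d - distance_m) < tol_m:
            return mid, lon
        if d < distance_m:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), lon
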