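"""Independent low-precision solar/lunar oracle for cross-checking.

These are the classical Astronomical Almanac low-precision formulae
(van Flandern & Pulkkinen class): a handful of trigonometric terms fitted
directly to the lunar and solar motion, with a sidereal-time expression and
altitude conversion written from scratch.  Stated accuracy is about 0.3 deg
for lunar ecliptic coordinates and 0.01 deg for the Sun — an independent
derivation path that bounds gross errors in the package ephemeris without
sharing any code or coefficient tables with it.

This module is test support, not part of the package.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6378.14


def _d(jd_utc):
    return np.asarray(jd_utc, dtype=float) - 2451545.0


def sun_ecliptic(jd_utc):
    """Solar geocentric apparent longitude (deg) and distance (AU)."""
    n = _d(jd_utc)
    L = 280.460 + 0.9856474 * n
    g = np.deg2rad(357.528 + 0.9856003 * n)
    lam = L + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g)
    R = 1.00014 - 0.01671 * np.cos(g) - 0.00014 * np.cos(2 * g)
    return np.remainder(lam, 360.0), R


def moon_ecliptic(jd_utc):
    """Lunar geocentric longitude, latitude (deg) and distance (km)."""
    T = _d(jd_utc) / 36525.0

    def s(a, b):
        return np.sin(np.deg2rad(a + b * T))

    def c(a, b):
        return np.cos(np.deg2rad(a + b * T))

    lam = (
        218.32 + 481267.881 * T
        + 6.29 * s(135.0, 477198.87)
        - 1.27 * s(259.3, -413335.36)
        + 0.66 * s(235.7, 890534.22)
        + 0.21 * s(269.9, 954397.74)
        - 0.19 * s(357.5, 35999.05)
        - 0.11 * s(186.5, 966404.03)
    )
    beta = (
        5.13 * s(93.3, 483202.02)
        + 0.28 * s(228.2, 960400.89)
        - 0.28 * s(318.3, 6003.15)
        - 0.17 * s(217.6, -407332.21)
    )
    # horizontal parallax in degrees
    par = (
        0.9508
        + 0.0518 * c(135.0, 477198.87)
        + 0.0095 * c(259.3, -413335.36)
        + 0.0078 * c(235.7, 890534.22)
        + 0.0028 * c(269.9, 954397.74)
    )
    dist = EARTH_RADIUS_KM / np.sin(np.deg2rad(par))
    return np.remainder(lam, 360.0), beta, dist


def _obliquity(jd_utc):
    return 23.439 - 0.0000004 * _d(jd_utc)


def ecl_to_radec(lam_deg, beta_deg, jd_utc):
    eps = np.deg2rad(_obliquity(jd_utc))
    lam = np.deg2rad(lam_deg)
    beta = np.deg2rad(beta_deg)
    x = np.cos(beta) * np.cos(lam)
    y = np.cos(eps) * np.cos(beta) * np.sin(lam) - np.sin(eps) * np.sin(beta)
    z = np.sin(eps) * np.cos(beta) * np.sin(lam) + np.cos(eps) * np.sin(beta)
    ra = np.rad2deg(np.arctan2(y, x)) % 360.0
    dec = np.rad2deg(np.arcsin(np.clip(z, -1, 1)))
    return ra, dec


def gmst_hours(jd_utc):
    # classical expression in hours (independent of the package's degree form)
    return np.remainder(18.697374558 + 24.06570982441908 * _d(jd_utc), 24.0)


def altitude(ra_deg, dec_deg, jd_utc, lat_deg, lon_deg):
    """Geocentric altitude (deg) of a body at RA/dec for an observer."""
    lst_deg = gmst_hours(jd_utc) * 15.0 + lon_deg
    H = np.deg2rad(lst_deg - ra_deg)
    phi = np.deg2rad(lat_deg)
    dec = np.deg2rad(dec_deg)
    sin_alt = np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.cos(H)
    return np.rad2deg(np.arcsin(np.clip(sin_alt, -1, 1)))


def moon_topocentric_altitude(jd_utc, lat_deg, lon_deg):
    lam, beta, dist = moon_ecliptic(jd_utc)
    ra, dec = ecl_to_radec(lam, beta, jd_utc)
    alt = altitude(ra, dec, jd_utc, lat_deg, lon_deg)
    par = np.rad2deg(np.arcsin(EARTH_RADIUS_KM / dist))
    return alt - par * np.cos(np.deg2rad(alt)), dist


def sun_altitude(jd_utc, lat_deg, lon_deg):
    lam, _ = sun_ecliptic(jd_utc)
    ra, dec = ecl_to_radec(lam, np.zeros_like(np.asarray(lam)), jd_utc)
    return altitude(ra, dec, jd_utc, lat_deg, lon_deg)


def phase_angle(jd_utc):
    """Geocentric phase angle (deg) from the two low-precision theories."""
    lam_m, beta_m, dist_m = moon_ecliptic(jd_utc)
    lam_s, R_s = sun_ecliptic(jd_utc)
    cos_psi = np.cos(np.deg2rad(beta_m)) * np.cos(np.deg2rad(lam_m - lam_s))
    psi = np.arccos(np.clip(cos_psi, -1, 1))
    R_km = R_s * 1.495978707e8
    return np.rad2deg(np.arctan2(R_km * np.sin(psi), dist_m - R_km * np.cos(psi)))
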