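"""Solar and lunar positions for a ground site, at schedule resolution.

Implements a medium-precision analytic ephemeris: the classical truncated
ELP-2000/82 periodic series for the Moon (~60 terms in longitude/distance and
latitude) and the standard low-order solar theory, with nutation reduced to
its two leading terms.  Accuracy is a few hundredths of a degree for the Moon
and better than 0.01 deg for the Sun — comfortably inside the 0.5 deg
contract that the downstream sky-brightness model needs.

All computation is in UTC internally; dynamical time is obtained from a
polynomial Delta-T model fitted to the 2005-2050 era.  Phase angle is
computed from geocentric Sun/Moon vectors (the standard convention for
illumination work); topocentric parallax is applied to the Moon's altitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone

import numpy as np

__all__ = [
    "GeoLocation",
    "SolarState",
    "LunarState",
    "PolarDayNight",
    "julian_day",
    "solar_position",
    "lunar_state",
    "sun_rise_set",
    "ephemeris_table",
    "MENAI_BRIDGE",
]

AU_KM = 1.495978707e8
EARTH_RADIUS_KM = 6378.14
MEAN_LUNAR_DISTANCE_KM = 384_400.0
J2000 = 2451545.0


@dataclass(frozen=True)
class GeoLocation:
    """Observer site: geodetic latitude/longitude (degrees, east positive)."""

    latitude_deg: float
    longitude_deg: float
    elevation_m: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude_deg <= 90.0:
            raise ValueError(f"latitude {self.latitude_deg} outside [-90, 90]")
        if not -180.0 <= self.longitude_deg <= 180.0:
            raise ValueError(f"longitude {self.longitude_deg} outside [-180, 180]")


#: The study site: Menai Bridge, UK (53d13'57" N, 4d10'22" W), sea level.
MENAI_BRIDGE = GeoLocation(
    latitude_deg=53.0 + 13.0 / 60 + 57.0 / 3600,
    longitude_deg=-(4.0 + 10.0 / 60 + 22.0 / 3600),
)


@dataclass(frozen=True)
class SolarState:
    altitude_deg: float
    azimuth_deg: float  # north = 0, east = 90


@dataclass(frozen=True)
class LunarState:
    altitude_deg: float  # topocentric (parallax-corrected), unrefracted
    azimuth_deg: float
    phase_angle_deg: float  # 0 = full, 180 = new
    illuminated_fraction: float
    distance_km: float  # centre-to-centre

    @property
    def zenith_deg(self) -> float:
        return 90.0 - self.altitude_deg


class PolarDayNight(Exception):
    """Raised when the sun does not cross the horizon on the requested date."""

    def __init__(self, kind: str, loc: GeoLocation, day: date):
        self.kind = kind  # "polar_day" or "polar_night"
        super().__init__(f"{kind} at lat {loc.latitude_deg:.2f} on {day}")


# ---------------------------------------------------------------------------
# time scales

def _to_utc_datetime(t: datetime) -> datetime:
    if not isinstance(t, datetime):
        raise TypeError(f"expected datetime, got {type(t).__name__}")
    if t.tzinfo is None:
        raise ValueError("timestamp must carry an explicit UTC offset")
    return t.astimezone(timezone.utc)


def julian_day(t: datetime) -> float:
    """Julian day (UTC) of an aware datetime."""
    t = _to_utc_datetime(t)
    epoch = datetime(2000, 1, 1, 12, 0, tzinfo=timezone.utc)  # JD 2451545.0
    return J2000 + (t - epoch).total_seconds() / 86400.0


def _delta_t_seconds(jd_utc):
    """TT - UTC, Espenak-Meeus style polynomial for the 2005-2050 era."""
    y = 2000.0 + (np.asarray(jd_utc, dtype=float) - J2000) / 365.25
    t = np.clip(y, 2005.0, 2050.0) - 2000.0
    return 62.92 + 0.32217 * t + 0.005589 * t * t


def _jd_tt(jd_utc):
    return np.asarray(jd_utc, dtype=float) + _delta_t_seconds(jd_utc) / 86400.0


# ---------------------------------------------------------------------------
# fundamental arguments and frames

_D2R = np.pi / 180.0


def _obliquity_deg(T):
    # mean obliquity, arcsecond polynomial
    return (
        23.0 + 26.0 / 60 + 21.448 / 3600
        - (46.8150 * T + 0.00059 * T**2 - 0.001813 * T**3) / 3600.0
    )


def _nutation_deg(T):
    """Leading nutation terms: (dpsi, deps) in degrees."""
    omega = np.deg2rad(125.04452 - 1934.136261 * T)
    l_sun = np.deg2rad(280.4665 + 36000.7698 * T)
    l_moon = np.deg2rad(218.3165 + 481267.8813 * T)
    dpsi = (
        -17.20 * np.sin(omega)
        - 1.32 * np.sin(2 * l_sun)
        - 0.23 * np.sin(2 * l_moon)
        + 0.21 * np.sin(2 * omega)
    ) / 3600.0
    deps = (
        9.20 * np.cos(omega)
        + 0.57 * np.cos(2 * l_sun)
        + 0.10 * np.cos(2 * l_moon)
        - 0.09 * np.cos(2 * omega)
    ) / 3600.0
    return dpsi, deps


def _gmst_deg(jd_utc):
    d = np.asarray(jd_utc, dtype=float) - J2000
    T = d / 36525.0
    theta = 280.46061837 + 360.98564736629 * d + 0.000387933 * T**2 - T**3 / 38710000.0
    return np.remainder(theta, 360.0)


def _ecl_to_equ(lam_deg, beta_deg, eps_deg):
    lam, beta, eps = (np.deg2rad(x) for x in (lam_deg, beta_deg, eps_deg))
    ra = np.arctan2(
        np.sin(lam) * np.cos(eps) - np.tan(beta) * np.sin(eps), np.cos(lam)
    )
    dec = np.arcsin(
        np.sin(beta) * np.cos(eps) + np.cos(beta) * np.sin(eps) * np.sin(lam)
    )
    return np.rad2deg(ra) % 360.0, np.rad2deg(dec)


def _equ_to_horizontal(ra_deg, dec_deg, jd_utc, loc: GeoLocation):
    """Apparent RA/dec -> (altitude, azimuth north=0/east=90), degrees."""
    T = (_jd_tt(jd_utc) - J2000) / 36525.0
    dpsi, _ = _nutation_deg(T)
    eps = _obliquity_deg(T)
    gast = _gmst_deg(jd_utc) + dpsi * np.cos(np.deg2rad(eps))
    H = np.deg2rad(np.remainder(gast + loc.longitude_deg - ra_deg, 360.0))
    phi = np.deg2rad(loc.latitude_deg)
    dec = np.deg2rad(dec_deg)
    alt = np.arcsin(np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.cos(H))
    # azimuth measured from south in the classical formula; shift to north-based
    az_south = np.arctan2(
        np.sin(H), np.cos(H) * np.sin(phi) - np.tan(dec) * np.cos(phi)
    )
    az = np.remainder(np.rad2deg(az_south) + 180.0, 360.0)
    return np.rad2deg(alt), az


# ---------------------------------------------------------------------------
# solar theory (low-order)

def _sun_geometric(jd_tt):
    """Geocentric true longitude (deg, of date), latitude ~ 0, distance (AU)."""
    T = (np.asarray(jd_tt, dtype=float) - J2000) / 36525.0
    L0 = 280.46646 + 36000.76983 * T + 0.0003032 * T**2
    M = 357.52911 + 35999.05029 * T - 0.0001537 * T**2
    e = 0.016708634 - 0.000042037 * T - 0.0000001267 * T**2
    Mr = np.deg2rad(M)
    C = (
        (1.914602 - 0.004817 * T - 0.000014 * T**2) * np.sin(Mr)
        + (0.019993 - 0.000101 * T) * np.sin(2 * Mr)
        + 0.000289 * np.sin(3 * Mr)
    )
    true_lon = np.remainder(L0 + C, 360.0)
    nu = np.deg2rad(M + C)
    R = 1.000001018 * (1 - e**2) / (1 + e * np.cos(nu))
    return true_lon, R


def _sun_apparent_radec(jd_utc):
    jd_tt = _jd_tt(jd_utc)
    T = (jd_tt - J2000) / 36525.0
    true_lon, R = _sun_geometric(jd_tt)
    omega = np.deg2rad(125.04 - 1934.136 * T)
    lam_app = true_lon - 0.00569 - 0.00478 * np.sin(omega)
    dpsi, deps = _nutation_deg(T)
    eps = _obliquity_deg(T) + deps
    ra, dec = _ecl_to_equ(lam_app, np.zeros_like(lam_app), eps)
    return ra, dec, R


def _sun_altaz(jd_utc, loc: GeoLocation):
    ra, dec, _ = _sun_apparent_radec(jd_utc)
    return _equ_to_horizontal(ra, dec, jd_utc, loc)


# ---------------------------------------------------------------------------
# lunar theory: truncated ELP-2000/82 periodic series
# columns: D, M, M', F multipliers; coefficient
# longitude coefficients in 1e-6 deg, distance in 1e-3 km, latitude in 1e-6 deg

_LR_TERMS = np.array([
    (0, 0, 1, 0, 6288774, -20905355),
    (2, 0, -1, 0, 1274027, -3699111),
    (2, 0, 0, 0, 658314, -2955968),
    (0, 0, 2, 0, 213618, -569925),
    (0, 1, 0, 0, -185116, 48888),
    (0, 0, 0, 2, -114332, -3149),
    (2, 0, -2, 0, 58793, 246158),
    (2, -1, -1, 0, 57066, -152138),
    (2, 0, 1, 0, 53322, -170733),
    (2, -1, 0, 0, 45758, -204586),
    (0, 1, -1, 0, -40923, -129620),
    (1, 0, 0, 0, -34720, 108743),
    (0, 1, 1, 0, -30383, 104755),
    (2, 0, 0, -2, 15327, 10321),
    (0, 0, 1, 2, -12528, 0),
    (0, 0, 1, -2, 10980, 79661),
    (4, 0, -1, 0, 10675, -34782),
    (0, 0, 3, 0, 10034, -23210),
    (4, 0, -2, 0, 8548, -21636),
    (2, 1, -1, 0, -7888, 24208),
    (2, 1, 0, 0, -6766, 30824),
    (1, 0, -1, 0, -5163, -8379),
    (1, 1, 0, 0, 4987, -16675),
    (2, -1, 1, 0, 4036, -12831),
    (2, 0, 2, 0, 3994, -10445),
    (4, 0, 0, 0, 3861, -11650),
    (2, 0, -3, 0, 3665, 14403),
    (0, 1, -2, 0, -2689, -7003),
    (2, 0, -1, 2, -2602, 0),
    (2, -1, -2, 0, 2390, 10056),
    (1, 0, 1, 0, -2348, 6322),
    (2, -2, 0, 0, 2236, -9884),
    (0, 1, 2, 0, -2120, 5751),
    (0, 2, 0, 0, -2069, 0),
    (2, -2, -1, 0, 2048, -4950),
    (2, 0, 1, -2, -1773, 4130),
    (2, 0, 0, 2, -1595, 0),
    (4, -1, -1, 0, 1215, -3958),
    (0, 0, 2, 2, -1110, 0),
    (3, 0, -1, 0, -892, 3258),
    (2, 1, 1, 0, -810, 2616),
    (4, -1, -2, 0, 759, -1897),
    (0, 2, -1, 0, -713, -2117),
    (2, 2, -1, 0, -700, 2354),
    (2, 1, -2, 0, 691, 0),
    (2, -1, 0, -2, 596, 0),
    (4, 0, 1, 0, 549, -1423),
    (0, 0, 4, 0, 537, -1117),
    (4, -1, 0, 0, 520, -1571),
    (1, 0, -2, 0, -487, -1739),
    (2, 1, 0, -2, -399, 0),
    (0, 0, 2, -2, -381, -4421),
    (1, 1, 1, 0, 351, 0),
    (3, 0, -2, 0, -340, 0),
    (4, 0, -3, 0, 330, 0),
    (2, -1, 2, 0, 327, 0),
    (0, 2, 1, 0, -323, 1165),
    (1, 1, -1, 0, 299, 0),
    (2, 0, 3, 0, 294, 0),
    (2, 0, -1, -2, 0, 8752),
], dtype=float)

_B_TERMS = np.array([
    (0, 0, 0, 1, 5128122),
    (0, 0, 1, 1, 280602),
    (0, 0, 1, -1, 277693),
    (2, 0, 0, -1, 173237),
    (2, 0, -1, 1, 55413),
    (2, 0, -1, -1, 46271),
    (2, 0, 0, 1, 32573),
    (0, 0, 2, 1, 17198),
    (2, 0, 1, -1, 9266),
    (0, 0, 2, -1, 8822),
    (2, -1, 0, -1, 8216),
    (2, 0, -2, -1, 4324),
    (2, 0, 1, 1, 4200),
    (2, 1, 0, -1, -3359),
    (2, -1, -1, 1, 2463),
    (2, -1, 0, 1, 2211),
    (2, -1, -1, -1, 2065),
    (0, 1, -1, -1, -1870),
    (4, 0, -1, -1, 1828),
    (0, 1, 0, 1, -1794),
    (0, 0, 0, 3, -1749),
    (0, 1, -1, 1, -1565),
    (1, 0, 0, 1, -1491),
    (0, 1, 1, 1, -1475),
    (0, 1, 1, -1, -1410),
    (0, 1, 0, -1, -1344),
    (1, 0, 0, -1, -1335),
    (0, 0, 3, 1, 1107),
    (4, 0, 0, -1, 1021),
    (4, 0, -1, 1, 833),
    (0, 0, 1, -3, 777),
    (4, 0, -2, 1, 671),
    (2, 0, 0, -3, 607),
    (2, 0, 2, -1, 596),
    (2, -1, 1, -1, 491),
    (2, 0, -2, 1, -451),
    (0, 0, 3, -1, 439),
    (2, 0, 2, 1, 422),
    (2, 0, -3, -1, 421),
    (2, 1, -1, 1, -366),
    (2, 1, 0, 1, -351),
    (4, 0, 0, 1, 331),
    (2, -1, 1, 1, 315),
    (2, -2, 0, -1, 302),
    (0, 0, 1, 3, -283),
    (2, 1, 1, -1, -229),
    (1, 1, 0, -1, 223),
    (1, 1, 0, 1, 223),
    (0, 1, -2, -1, -220),
    (2, 1, -1, -1, -220),
    (1, 0, 1, 1, -185),
    (2, -1, -2, -1, 181),
    (0, 1, 2, 1, -177),
    (4, 0, -2, -1, 176),
    (4, -1, -1, -1, 166),
    (1, 0, 1, -1, -164),
    (4, 0, 1, -1, 132),
    (1, 0, -2, -1, -119),
    (4, -1, 0, -1, 115),
    (2, -2, 0, 1, 107),
], dtype=float)


def _moon_geocentric(jd_tt):
    """Geocentric ecliptic lon/lat (deg, mean equinox of date) and distance (km)."""
    T = (np.asarray(jd_tt, dtype=float) - J2000) / 36525.0
    Lp = (
        218.3164477 + 481267.88123421 * T - 0.0015786 * T**2
        + T**3 / 538841.0 - T**4 / 65194000.0
    )
    D = (
        297.8501921 + 445267.1114034 * T - 0.0018819 * T**2
        + T**3 / 545868.0 - T**4 / 113065000.0
    )
    M = 357.5291092 + 35999.0502909 * T - 0.0001536 * T**2 + T**3 / 24490000.0
    Mp = (
        134.9633964 + 477198.8675055 * T + 0.0087414 * T**2
        + T**3 / 69699.0 - T**4 / 14712000.0
    )
    F = (
        93.2720950 + 483202.0175233 * T - 0.0036539 * T**2
        - T**3 / 3526000.0 + T**4 / 863310000.0
    )
    A1 = 119.75 + 131.849 * T
    A2 = 53.09 + 479264.290 * T
    A3 = 313.45 + 481266.484 * T
    E = 1.0 - 0.002516 * T - 0.0000074 * T**2

    args = (D, M, Mp, F)

    def _series(table, coeff_col):
        mult = table[:, :4]  # (n_terms, 4)
        coeff = table[:, coeff_col]
        # eccentricity damping for terms involving the solar anomaly
        e_pow = np.abs(mult[:, 1])
        phases = sum(
            np.multiply.outer(np.deg2rad(a), mult[:, i]) for i, a in enumerate(args)
        )  # (..., n_terms)
        damping = E[..., np.newaxis] ** e_pow if np.ndim(E) else E**e_pow
        return phases, coeff, damping

    ph, cl, dampl = _series(_LR_TERMS, 4)
    sum_l = np.sum(cl * dampl * np.sin(ph), axis=-1)
    _, cr, _ = _series(_LR_TERMS, 5)
    sum_r = np.sum(cr * dampl * np.cos(ph), axis=-1)
    phb, cb, dampb = _series(_B_TERMS, 4)
    sum_b = np.sum(cb * dampb * np.sin(phb), axis=-1)

    a1r, a2r, a3r = (np.deg2rad(x) for x in (A1, A2, A3))
    lpr, fr, mpr = np.deg2rad(Lp), np.deg2rad(F), np.deg2rad(Mp)
    sum_l = sum_l + 3958 * np.sin(a1r) + 1962 * np.sin(lpr - fr) + 318 * np.sin(a2r)
    sum_b = (
        sum_b
        - 2235 * np.sin(lpr)
        + 382 * np.sin(a3r)
        + 175 * np.sin(a1r - fr)
        + 175 * np.sin(a1r + fr)
        + 127 * np.sin(lpr - mpr)
        - 115 * np.sin(lpr + mpr)
    )

    lon = np.remainder(Lp + sum_l / 1e6, 360.0)
    lat = sum_b / 1e6
    dist = 385000.56 + sum_r / 1e3
    return lon, lat, dist


def _moon_apparent_radec(jd_utc):
    jd_tt = _jd_tt(jd_utc)
    T = (jd_tt - J2000) / 36525.0
    lon, lat, dist = _moon_geocentric(jd_tt)
    dpsi, deps = _nutation_deg(T)
    eps = _obliquity_deg(T) + deps
    ra, dec = _ecl_to_equ(lon + dpsi, lat, eps)
    return ra, dec, dist


def _phase_angle_deg(jd_utc):
    """Geocentric phase angle (deg) and lunar distance (km)."""
    jd_tt = _jd_tt(jd_utc)
    lon_m, lat_m, dist_m = _moon_geocentric(jd_tt)
    lon_s, R_s = _sun_geometric(jd_tt)
    # geocentric elongation
    cos_psi = np.cos(np.deg2rad(lat_m)) * np.cos(np.deg2rad(lon_m - lon_s))
    psi = np.arccos(np.clip(cos_psi, -1.0, 1.0))
    R_km = R_s * AU_KM
    alpha = np.arctan2(R_km * np.sin(psi), dist_m - R_km * np.cos(psi))
    return np.rad2deg(alpha), dist_m


def illuminated_fraction(phase_angle_deg):
    """f = (1 + cos(alpha)) / 2."""
    return (1.0 + np.cos(np.deg2rad(phase_angle_deg))) / 2.0


def _moon_altaz(jd_utc, loc: GeoLocation):
    ra, dec, dist = _moon_apparent_radec(jd_utc)
    alt_geo, az = _equ_to_horizontal(ra, dec, jd_utc, loc)
    # topocentric altitude: subtract the parallax in altitude
    hp = np.rad2deg(np.arcsin(EARTH_RADIUS_KM / dist))
    alt_topo = alt_geo - hp * np.cos(np.deg2rad(alt_geo))
    return alt_topo, az, dist


# ---------------------------------------------------------------------------
# public scalar interface

def solar_position(loc: GeoLocation, t: datetime) -> SolarState:
    """Unrefracted solar altitude/azimuth at an aware datetime."""
    jd = julian_day(t)
    alt, az = _sun_altaz(jd, loc)
    return SolarState(altitude_deg=float(alt), azimuth_deg=float(az))


def lunar_state(loc: GeoLocation, t: datetime) -> LunarState:
    """Topocentric lunar altitude/azimuth plus phase geometry."""
    jd = julian_day(t)
    alt, az, dist = _moon_altaz(jd, loc)
    alpha, _ = _phase_angle_deg(jd)
    return LunarState(
        altitude_deg=float(alt),
        azimuth_deg=float(az),
        phase_angle_deg=float(alpha),
        illuminated_fraction=float(illuminated_fraction(alpha)),
        distance_km=float(dist),
    )


_RISE_SET_ALT = -0.8333  # refraction + semi-diameter, conventional


def sun_rise_set(loc: GeoLocation, day: date) -> tuple[datetime, datetime]:
    """Sunrise and sunset (UTC) on a civil UTC date.

    Raises PolarDayNight when the sun stays above/below the horizon.
    The conventional refracted-limb altitude of -0.8333 deg defines the events.
    """
    start = datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
    jd0 = julian_day(start)
    minutes = np.arange(0, 24 * 60 + 1)
    jd = jd0 + minutes / 1440.0
    alt, _ = _sun_altaz(jd, loc)
    above = alt > _RISE_SET_ALT
    if above.all():
        raise PolarDayNight("polar_day", loc, day)
    if not above.any():
        raise PolarDayNight("polar_night", loc, day)

    def _cross(i: int) -> datetime:
        # linear interpolation between minute samples
        a0, a1 = alt[i], alt[i + 1]
        frac = (_RISE_SET_ALT - a0) / (a1 - a0)
        return start + timedelta(minutes=float(minutes[i] + frac))

    rises = [i for i in range(len(alt) - 1) if alt[i] <= _RISE_SET_ALT < alt[i + 1]]
    sets = [i for i in range(len(alt) - 1) if alt[i] > _RISE_SET_ALT >= alt[i + 1]]
    if not rises or not sets:
        raise PolarDayNight("polar_day" if above[0] else "polar_night", loc, day)
    return _cross(rises[0]), _cross(sets[0])


def ephemeris_table(loc: GeoLocation, times: "np.ndarray | list[datetime]"):
    """Vectorized ephemeris over a sequence of aware datetimes.

    Returns a pandas DataFrame with columns timestamp_utc, sun_alt, moon_alt,
    moon_az, phase_angle, illum_fraction, distance_km.
    """
    import pandas as pd

    idx = pd.DatetimeIndex(times)
    if idx.tz is None:
        raise ValueError("timestamps must be timezone-aware")
    idx = idx.tz_convert("UTC")
    if len(idx) == 0:
        raise ValueError("empty time grid")
    jd = J2000 + (idx.values.astype("datetime64[ns]").astype(np.int64) / 1e9
                  - 946728000.0) / 86400.0
    sun_alt, _ = _sun_altaz(jd, loc)
    moon_alt, moon_az, dist = _moon_altaz(jd, loc)
    alpha, _ = _phase_angle_deg(jd)
    return pd.DataFrame(
        {
            "timestamp_utc": idx,
            "sun_alt": sun_alt,
            "moon_alt": moon_alt,
            "moon_az": moon_az,
            "phase_angle": alpha,
            "illum_fraction": illuminated_fraction(alpha),
            "distance_km": dist,
        }
    )
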