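"""Solar geometry, diffuse/direct partitioning, slope transposition and
reference evapotranspiration.

All angles are handled in radians internally; degrees appear only at I/O
boundaries.  The azimuth convention throughout is *south-zero*: an azimuth
of 0 points due south, angles east of south are negative and west of south
positive.  This matches the convention used for vineyard aspect angles.

The module is fully vectorised: every function accepts scalars or numpy
arrays and broadcasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Solar constant (W m-2)
SOLAR_CONSTANT = 1367.0

#: Solar constant in MJ m-2 min-1, as used in daily radiation sums
SOLAR_CONSTANT_MJ_MIN = 0.0820

#: Stefan-Boltzmann constant (MJ K-4 m-2 day-1)
STEFAN_BOLTZMANN_MJ = 4.903e-9

#: Reference-surface short-wave albedo of the Penman-Monteith crop
REFERENCE_ALBEDO = 0.23

#: Floor on cos(zenith) used in the beam ratio of the transposition model,
#: preventing the geometric factor from blowing up at grazing sun angles
#: (cos of 85 degrees).
_COS_ZENITH_FLOOR = np.cos(np.deg2rad(85.0))


@dataclass(frozen=True)
class SolarPosition:
    """Sun position: zenith angle and south-zero azimuth, radians.

    ``zenith`` may exceed pi/2 when the sun is below the horizon.
    Fields may be scalars or numpy arrays.
    """

    zenith: np.ndarray | float
    azimuth: np.ndarray | float


@dataclass(frozen=True)
class SlopeSpec:
    """Terrain orientation: slope angle ``beta`` and aspect azimuth
    ``aspect`` (direction the slope faces, south-zero convention), radians."""

    beta: float
    aspect: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta < np.pi / 2:
            raise ValueError(f"slope angle must be in [0, pi/2), got {self.beta}")


@dataclass(frozen=True)
class DailyEt0:
    """Daily reference evapotranspiration on the slope surface (``et0s``)
    and its horizontal equivalent (``et0 = et0s / cos(beta)``), mm/day."""

    et0s: np.ndarray | float
    et0: np.ndarray | float


def _time_components(times) -> tuple[np.ndarray, np.ndarray]:
    """Return (day-of-year, fractional UTC hour) for datetime-like input."""
    idx = pd.DatetimeIndex(np.atleast_1d(np.asarray(times, dtype="object")))
    if idx.tz is not None:
        idx = idx.tz_convert("UTC").tz_localize(None)
    doy = idx.dayofyear.to_numpy(dtype=float)
    hour = (
        idx.hour.to_numpy(dtype=float)
        + idx.minute.to_numpy(dtype=float) / 60.0
        + idx.second.to_numpy(dtype=float) / 3600.0
    )
    return doy, hour


def _day_angle(doy: np.ndarray, hour: np.ndarray) -> np.ndarray:
    return 2.0 * np.pi * (doy - 1.0 + (hour - 12.0) / 24.0) / 365.0


def declination(day_angle: np.ndarray) -> np.ndarray:
    """Solar declination (rad), Spencer Fourier series."""
    g = day_angle
    return (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )


def eccentricity_factor(day_angle: np.ndarray) -> np.ndarray:
    """Squared ratio of mean to actual sun-earth distance (dimensionless)."""
    g = day_angle
    return (
        1.000110
        + 0.034221 * np.cos(g)
        + 0.001280 * np.sin(g)
        + 0.000719 * np.cos(2 * g)
        + 0.000077 * np.sin(2 * g)
    )


def equation_of_time(day_angle: np.ndarray) -> np.ndarray:
    """Equation of time in minutes (Spencer)."""
    g = day_angle
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.04089 * np.sin(2 * g)
    )


def solar_position(latitude: float, longitude: float, times) -> SolarPosition:
    """Sun zenith and south-zero azimuth for UTC instants.

    Parameters
    ----------
    latitude, longitude : float
        Site coordinates in radians; longitude positive east.
    times : datetime-like, sequence or DatetimeIndex
        Instants; tz-naive values are interpreted as UTC.
    """
    if not abs(latitude) < np.pi / 2:
        raise ValueError("latitude must lie strictly between the poles")
    doy, hour = _time_components(times)
    g = _day_angle(doy, hour)
    dec = declination(g)
    eot = equation_of_time(g)
    # true solar time in hours
    tst = hour + np.rad2deg(longitude) / 15.0 + eot / 60.0
    omega = np.deg2rad((tst - 12.0) * 15.0)
    # wrap hour angle into (-pi, pi]
    omega = (omega + np.pi) % (2 * np.pi) - np.pi

    sin_lat, cos_lat = np.sin(latitude), np.cos(latitude)
    cos_z = sin_lat * np.sin(dec) + cos_lat * np.cos(dec) * np.cos(omega)
    cos_z = np.clip(cos_z, -1.0, 1.0)
    zenith = np.arccos(cos_z)
    sin_z = np.sin(zenith)

    with np.errstate(divide="ignore", invalid="ignore"):
        cos_az = (cos_z * sin_lat - np.sin(dec)) / (sin_z * cos_lat)
    cos_az = np.where(sin_z < 1e-9, 1.0, np.clip(cos_az, -1.0, 1.0))
    azimuth = np.sign(omega) * np.abs(np.arccos(cos_az))

    if np.isscalar(times) or getattr(times, "ndim", 1) == 0:
        return SolarPosition(float(zenith[0]), float(azimuth[0]))
    return SolarPosition(zenith, azimuth)


def cos_incidence(sun: SolarPosition, slope: SlopeSpec) -> np.ndarray | float:
    """Cosine of the angle between the solar beam and the slope normal.

    May be negative when the sun is behind the slope plane.
    """
    return np.cos(sun.zenith) * np.cos(slope.beta) + np.sin(sun.zenith) * np.sin(
        slope.beta
    ) * np.cos(sun.azimuth - slope.aspect)


def incidence_angle(sun: SolarPosition, slope: SlopeSpec) -> np.ndarray | float:
    """Angle of incidence on the slope plane, in [0, pi]."""
    return np.arccos(np.clip(cos_incidence(sun, slope), -1.0, 1.0))


def extraterrestrial_radiation(
    latitude: float,
    times,
    slope: SlopeSpec | None = None,
    longitude: float = 0.0,
) -> np.ndarray | float:
    """Instantaneous extraterrestrial irradiance (W m-2) on the horizontal
    or, if ``slope`` is given, on the slope plane.

    Zero whenever the sun is below the horizon or behind the slope plane.
    """
    sun = solar_position(latitude, longitude, times)
    doy, hour = _time_components(times)
    e0 = eccentricity_factor(_day_angle(doy, hour))
    cos_z = np.cos(np.asarray(sun.zenith))
    if slope is None or slope.beta == 0.0:
        r0 = SOLAR_CONSTANT * e0 * np.maximum(cos_z, 0.0)
    else:
        cos_t = np.asarray(cos_incidence(sun, slope))
        r0 = SOLAR_CONSTANT * e0 * np.where(cos_z > 0.0, np.maximum(cos_t, 0.0), 0.0)
    if np.isscalar(times) or getattr(times, "ndim", 1) == 0:
        return float(np.asarray(r0).ravel()[0])
    return r0


def daily_extraterrestrial(latitude: float, doy) -> np.ndarray | float:
    """Daily extraterrestrial radiation on the horizontal, MJ m-2 d-1
    (closed-form daylight integral)."""
    doy = np.asarray(doy, dtype=float)
    g = 2.0 * np.pi * (doy - 1.0) / 365.0
    dec = declination(g)
    dr = eccentricity_factor(g)
    x = np.clip(-np.tan(latitude) * np.tan(dec), -1.0, 1.0)
    ws = np.arccos(x)
    ra = (
        24.0
        * 60.0
        / np.pi
        * SOLAR_CONSTANT_MJ_MIN
        * dr
        * (
            ws * np.sin(latitude) * np.sin(dec)
            + np.cos(latitude) * np.cos(dec) * np.sin(ws)
        )
    )
    return np.maximum(ra, 0.0)


# ---------------------------------------------------------------------------
# Diffuse fraction
# ---------------------------------------------------------------------------

#: Default clearness-index correlation: Erbs-type piecewise polynomial.
#: (kt_low, kt_high, clear-sky floor, polynomial coefficients low->high order)
ERBS_KT_LOW = 0.22
ERBS_KT_HIGH = 0.80
ERBS_CLEAR_SKY_FLOOR = 0.165
ERBS_POLY = (0.9511, -0.1604, 4.388, -16.638, 12.336)


def diffuse_fraction(
    kt,
    poly: tuple = ERBS_POLY,
    kt_low: float = ERBS_KT_LOW,
    kt_high: float = ERBS_KT_HIGH,
    floor: float = ERBS_CLEAR_SKY_FLOOR,
) -> np.ndarray | float:
    """Diffuse fraction of global radiation from the clearness index.

    Piecewise correlation of the Erbs family.  The polynomial branch is
    clipped from below at the clear-sky floor, which renders the curve
    monotone non-increasing over its whole domain (the raw quartic has a
    shallow spurious dip just below the floor near its upper boundary).

    Parameters may be overridden to substitute locally fitted coefficients.
    """
    kt_arr = np.asarray(kt, dtype=float)
    if np.any(kt_arr < 0):
        raise ValueError("clearness index must be non-negative")
    k = np.clip(kt_arr, 0.0, 1.2)

    linear = 1.0 - 0.09 * k
    p = np.polynomial.polynomial.polyval(k, np.asarray(poly))
    poly_branch = np.clip(p, floor, 1.0)
    fd = np.where(k <= kt_low, linear, np.where(k <= kt_high, poly_branch, floor))
    fd = np.clip(fd, 0.0, 1.0)
    if np.isscalar(kt):
        return float(fd)
    return fd


# ---------------------------------------------------------------------------
# Transposition to the slope plane (HDKR)
# ---------------------------------------------------------------------------


def transpose_to_slope(
    r_glob,
    r_dir,
    r_dif,
    r0_horizontal,
    sun: SolarPosition,
    slope: SlopeSpec,
    ground_albedo: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Project horizontal irradiance components onto the slope plane with the
    anisotropic HDKR model.

    Returns ``(beam_poa, diffuse_poa)`` in W m-2, where ``beam_poa`` bundles
    the directional components (beam + circumsolar diffuse, travelling along
    the sun direction) and ``diffuse_poa`` the isotropic + horizon-brightening
    sky diffuse plus ground-reflected irradiance.  Their sum is the global
    irradiance in the plane of the slope.

    At ``beta == 0`` the inputs are returned unchanged (bit-for-bit), so a
    flat "slope" is exactly the horizontal pipeline.
    """
    r_glob = np.asarray(r_glob, dtype=float)
    r_dir = np.asarray(r_dir, dtype=float)
    r_dif = np.asarray(r_dif, dtype=float)
    if slope.beta == 0.0:
        return r_dir.copy(), r_dif.copy()

    r0 = np.asarray(r0_horizontal, dtype=float)
    cos_z = np.cos(np.asarray(sun.zenith))
    cos_t = np.asarray(cos_incidence(sun, slope))
    sun_up = cos_z > 0.0

    # geometric beam ratio, with a floor on cos(zenith) near the horizon
    rb = np.where(
        sun_up & (cos_t > 0.0),
        np.maximum(cos_t, 0.0) / np.maximum(cos_z, _COS_ZENITH_FLOOR),
        0.0,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where((r0 > 0.0) & sun_up, r_dir / np.maximum(r0, 1e-12), 0.0)
        f_hb = np.sqrt(np.where(r_glob > 0.0, r_dir / np.maximum(r_glob, 1e-12), 0.0))
    ai = np.clip(ai, 0.0, 1.0)

    beam_poa = (r_dir + r_dif * ai) * rb
    iso = (
        r_dif
        * (1.0 - ai)
        * (1.0 + np.cos(slope.beta))
        / 2.0
        * (1.0 + f_hb * np.sin(slope.beta / 2.0) ** 3)
    )
    ground = r_glob * ground_albedo * (1.0 - np.cos(slope.beta)) / 2.0
    diffuse_poa = iso + ground
    return np.maximum(beam_poa, 0.0), np.maximum(diffuse_poa, 0.0)


# ---------------------------------------------------------------------------
# Reference evapotranspiration (Penman-Monteith, daily)
# ---------------------------------------------------------------------------


def saturation_vapour_pressure(t_celsius) -> np.ndarray | float:
    """Saturation vapour pressure (kPa) at air temperature (deg C)."""
    t = np.asarray(t_celsius, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def net_radiation_slope(
    tmin,
    tmax,
    rh,
    rs_slope_mj,
    ra_slope_mj,
    elevation: float = 100.0,
) -> np.ndarray | float:
    """Daily net radiation (MJ m-2 d-1) at the slope surface.

    Short-wave: reference-crop albedo applied to the slope-plane solar sum.
    Long-wave: clear-sky emissivity formulation driven by the relative
    clearness ``Rs/Rso`` on the slope plane; terrain long-wave exchange is
    neglected (sky-view simplification; for slopes up to ~35 degrees the
    effect on potential evapotranspiration is of order one percent).
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    rs = np.asarray(rs_slope_mj, dtype=float)
    ra = np.asarray(ra_slope_mj, dtype=float)

    ea = np.asarray(rh, dtype=float) / 100.0 * (
        saturation_vapour_pressure(tmax) + saturation_vapour_pressure(tmin)
    ) / 2.0
    rns = (1.0 - REFERENCE_ALBEDO) * rs
    rso = (0.75 + 2e-5 * elevation) * ra
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(rso > 0.05, rs / np.maximum(rso, 1e-9), 0.5)
    rel = np.clip(rel, 0.25, 1.0)
    tk4 = ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0
    rnl = (
        STEFAN_BOLTZMANN_MJ
        * tk4
        * (0.34 - 0.14 * np.sqrt(np.maximum(ea, 0.0)))
        * (1.35 * rel - 0.35)
    )
    return rns - rnl


def et0_fao56(
    tmin,
    tmax,
    tmean,
    rh,
    u2,
    net_radiation_mj,
    beta: float = 0.0,
    elevation: float = 100.0,
) -> DailyEt0:
    """Daily reference evapotranspiration (Penman-Monteith combination
    equation) driven by net radiation at the slope surface.

    Returns the value referred to the slope surface (``et0s``) and its
    horizontal equivalent (``et0``), so it is commensurate with
    precipitation measured per unit horizontal area.
    """
    for name, val in (("rh", rh), ("u2", u2)):
        arr = np.asarray(val, dtype=float)
        if np.any(~np.isfinite(arr)):
            raise ValueError(f"missing or non-finite values in weather field '{name}'")
        if name == "rh" and (np.any(arr < 0) or np.any(arr > 100)):
            raise ValueError("relative humidity 'rh' must be within [0, 100] %")
        if name == "u2" and np.any(arr < 0):
            raise ValueError("wind speed 'u2' must be non-negative")

    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    t = np.asarray(tmean, dtype=float)
    rn = np.asarray(net_radiation_mj, dtype=float)
    u2 = np.asarray(u2, dtype=float)

    es = (saturation_vapour_pressure(tmax) + saturation_vapour_pressure(tmin)) / 2.0
    ea = np.asarray(rh, dtype=float) / 100.0 * es
    delta = 4098.0 * saturation_vapour_pressure(t) / (t + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    gamma = 0.000665 * pressure

    num = 0.408 * delta * rn + gamma * 900.0 / (t + 273.0) * u2 * (es - ea)
    et0s = np.maximum(num / (delta + gamma * (1.0 + 0.34 * u2)), 0.0)
    return DailyEt0(et0s=et0s, et0=horizontal_equivalent(et0s, beta))


def horizontal_equivalent(et0s, beta: float) -> np.ndarray | float:
    """Re-project a slope-surface water flux to its horizontal equivalent:
    ``ET0 = ET0s / cos(beta)``."""
    if not 0.0 <= beta < np.pi / 2:
        raise ValueError(f"slope angle must be in [0, pi/2), got {beta}")
    if beta == 0.0:
        return et0s
    return np.asarray(et0s, dtype=float) / np.cos(beta)
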