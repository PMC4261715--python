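"""End-to-end drivers: sub-daily irradiance on the slope, daily reference
evapotranspiration, the coupled radiation + water-balance season run, and
the slope x aspect evapotranspiration experiment.

The radiation chain per 30-min step: disaggregate the daily global
radiation along the extraterrestrial envelope, split diffuse/direct with
the clearness-index correlation, project both onto the slope plane
(anisotropic transposition), rotate the sun into the vineyard-local frame
and look up Monte Carlo absorbed fractions from an interception table that
is rebuilt whenever the phenology has changed the canopy appreciably.
Daily energy-weighted fractions f_R_v / f_R_s and the slope-aware ET0 then
drive the daily water balance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import solar
from .canopy import canopy_state_on, develop_canopy, thermal_time
from .config import SiteConfig
from .transport import InterceptionTable, local_sun_angles
from .waterbalance import SoilParams, cover_crop_calendar, run_water_balance

_STEPS_PER_DAY = 48
_DT_HOURS = 0.5


def subdaily_irradiance(weather: pd.DataFrame, latitude: float, longitude: float) -> dict:
    """Horizontal 30-min irradiance components for every day of a weather
    series.

    Returns a dict of flat arrays (length ``n_days * 48``): timestamps,
    horizontal global/direct/diffuse irradiance (W m-2), extraterrestrial
    irradiance, solar position and the per-day clearness index.
    """
    dates = pd.DatetimeIndex(weather.index)
    n_days = len(dates)
    times = pd.date_range(
        dates[0], periods=n_days * _STEPS_PER_DAY, freq=f"{int(_DT_HOURS * 60)}min"
    )
    sun = solar.solar_position(latitude, longitude, times)
    r0 = np.asarray(
        solar.extraterrestrial_radiation(latitude, times, longitude=longitude)
    )

    ra_daily = np.asarray(solar.daily_extraterrestrial(latitude, dates.dayofyear))
    rglob_daily = weather["rglob"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        kt = np.where(ra_daily > 0, rglob_daily / ra_daily, 0.0)
    kt = np.clip(kt, 0.0, 1.2)

    # scale the extraterrestrial shape so each day integrates exactly to
    # the daily total
    r0_by_day = r0.reshape(n_days, _STEPS_PER_DAY)
    day_mj = r0_by_day.sum(axis=1) * _DT_HOURS * 3600.0 / 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(day_mj > 0, rglob_daily / day_mj, 0.0)
    rglob = (r0_by_day * scale[:, None]).ravel()

    fd = np.asarray(solar.diffuse_fraction(kt))
    fd_flat = np.repeat(fd, _STEPS_PER_DAY)
    rdif = rglob * fd_flat
    rdir = rglob - rdif
    return {
        "times": times,
        "n_days": n_days,
        "dates": dates,
        "theta_z": np.asarray(sun.zenith),
        "gamma_s": np.asarray(sun.azimuth),
        "r0": r0,
        "rglob": rglob,
        "rdir": rdir,
        "rdif": rdif,
        "kt_daily": kt,
    }


def _slope_components(split: dict, slope: solar.SlopeSpec, albedo: float):
    sun = solar.SolarPosition(split["theta_z"], split["gamma_s"])
    beam, diff = solar.transpose_to_slope(
        split["rglob"], split["rdir"], split["rdif"], split["r0"], sun, slope, albedo
    )
    if slope.beta == 0.0:
        r0_slope = split["r0"]
    else:
        cos_t = np.asarray(solar.cos_incidence(sun, slope))
        cos_z = np.cos(split["theta_z"])
        with np.errstate(divide="ignore", invalid="ignore"):
            r0_slope = np.where(
                (cos_z > 0) & (split["r0"] > 0),
                split["r0"] / np.maximum(cos_z, 1e-9) * np.maximum(cos_t, 0.0),
                0.0,
            )
    return beam, diff, r0_slope


def daily_et0(
    weather: pd.DataFrame,
    latitude: float,
    longitude: float,
    slope: solar.SlopeSpec,
    elevation: float = 100.0,
    albedo: float = 0.2,
    split: dict | None = None,
) -> pd.DataFrame:
    """Daily reference evapotranspiration with slope-corrected radiation.

    Returns a frame with ``ET0s`` (slope surface) and ``ET0`` (horizontal
    equivalent), mm/day.
    """
    if split is None:
        split = subdaily_irradiance(weather, latitude, longitude)
    beam, diff, r0_slope = _slope_components(split, slope, albedo)
    n_days = split["n_days"]
    to_mj = _DT_HOURS * 3600.0 / 1e6
    rs_slope = (beam + diff).reshape(n_days, _STEPS_PER_DAY).sum(axis=1) * to_mj
    ra_slope = r0_slope.reshape(n_days, _STEPS_PER_DAY).sum(axis=1) * to_mj
    rn = solar.net_radiation_slope(
        weather["tmin"], weather["tmax"], weather["rh"], rs_slope, ra_slope, elevation
    )
    res = solar.et0_fao56(
        weather["tmin"],
        weather["tmax"],
        weather["tmean"],
        weather["rh"],
        weather["u2"],
        rn,
        beta=slope.beta,
        elevation=elevation,
    )
    return pd.DataFrame(
        {"ET0s": np.asarray(res.et0s), "ET0": np.asarray(res.et0)},
        index=weather.index,
    )


def _quantize_canopy(h, l, p0):
    """Round the canopy state so interception tables are shared between
    days with near-identical geometry."""
    return (round(h / 0.1) * 0.1, round(l / 0.1) * 0.1, round(p0 / 0.05) * 0.05)


def radiation_fractions(
    site: SiteConfig,
    weather: pd.DataFrame,
    n_photons: int = 20000,
    seed: int = 0,
    split: dict | None = None,
) -> pd.DataFrame:
    """Daily energy-weighted absorbed-radiation fractions f_R_v / f_R_s.

    Builds one Monte Carlo interception table per distinct (quantised)
    canopy state of the season and evaluates every 30-min step through it.
    All-dark days reuse the previous day's fractions.
    """
    if split is None:
        split = subdaily_irradiance(weather, site.latitude, site.longitude)
    dates = split["dates"]
    n_days = split["n_days"]

    tt = thermal_time(
        weather["tmean"].to_numpy(), dates, site.phenology.base_temperature
    )
    h_arr, l_arr, p0_arr = develop_canopy(tt, site.phenology, site.canopy)

    beam, diff, _ = _slope_components(split, site.slope, site.ground_albedo)
    theta_l, gamma_v = local_sun_angles(
        split["theta_z"], split["gamma_s"], site.slope, site.canopy.row_azimuth
    )

    keys = [_quantize_canopy(h_arr[i], l_arr[i], p0_arr[i]) for i in range(n_days)]
    tables: dict[tuple, InterceptionTable] = {}
    for i, key in enumerate(keys):
        if key not in tables:
            geom = canopy_state_on(site.canopy, *key)
            tables[key] = InterceptionTable.build(
                geom, site.optics, n=n_photons, seed=seed + len(tables)
            )

    r_v_steps = np.zeros(n_days * _STEPS_PER_DAY)
    r_s_steps = np.zeros(n_days * _STEPS_PER_DAY)
    day_of_step = np.repeat(np.arange(n_days), _STEPS_PER_DAY)
    for key, table in tables.items():
        day_mask = np.array([k == key for k in keys])
        mask = day_mask[day_of_step]
        a_v, a_s = table.query(theta_l[mask], gamma_v[mask])
        sun_up = theta_l[mask] < np.pi / 2
        b = beam[mask] * sun_up
        r_v_steps[mask] = a_v * b + table.a_dif_v * diff[mask]
        r_s_steps[mask] = a_s * b + table.a_dif_s * diff[mask]

    r_v_day = r_v_steps.reshape(n_days, _STEPS_PER_DAY).sum(axis=1)
    r_s_day = r_s_steps.reshape(n_days, _STEPS_PER_DAY).sum(axis=1)
    r_vy_day = r_v_day + r_s_day

    f_r_v = np.zeros(n_days)
    f_r_s = np.ones(n_days)
    defined = r_vy_day > 0
    prev = (0.0, 1.0)
    for i in range(n_days):
        if defined[i]:
            prev = (r_v_day[i] / r_vy_day[i], r_s_day[i] / r_vy_day[i])
        f_r_v[i], f_r_s[i] = prev
    return pd.DataFrame(
        {
            "f_R_v": f_r_v,
            "f_R_s": f_r_s,
            "defined": defined,
            "H": h_arr,
            "L": l_arr,
            "p0": p0_arr,
        },
        index=weather.index,
    )


def simulate_season(
    site: SiteConfig,
    weather: pd.DataFrame,
    n_photons: int = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full coupled run: radiation partitioning, slope-aware ET0 and the
    daily two-reservoir water balance, one output row per day."""
    split = subdaily_irradiance(weather, site.latitude, site.longitude)
    fractions = radiation_fractions(site, weather, n_photons, seed, split=split)
    et0 = daily_et0(
        weather,
        site.latitude,
        site.longitude,
        site.slope,
        site.elevation_m,
        site.ground_albedo,
        split=split,
    )
    calendar = cover_crop_calendar(weather.index, weather["tmin"].to_numpy())
    daily = run_water_balance(
        site.soil,
        weather.index,
        weather["precip"].to_numpy(),
        et0["ET0"].to_numpy(),
        fractions["f_R_v"].to_numpy(),
        fractions["f_R_s"].to_numpy(),
        calendar=calendar,
    )
    daily["ET0s"] = et0["ET0s"].to_numpy()
    for col in ("H", "L", "p0"):
        daily[col] = fractions[col].to_numpy()
    return daily


# ---------------------------------------------------------------------------
# Slope x aspect sensitivity experiment
# ---------------------------------------------------------------------------

DEFAULT_ASPECTS = (("S", 0.0), ("SW/SE", 45.0), ("W/E", 90.0), ("NW/NE", 135.0), ("N", 180.0))
DEFAULT_INCLINATIONS = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


def et0_slope_aspect_matrix(
    weather: pd.DataFrame,
    latitude_deg: float = 50.0,
    longitude_deg: float = 8.0,
    elevation: float = 100.0,
    albedo: float = 0.2,
    inclinations_deg=DEFAULT_INCLINATIONS,
    aspects=DEFAULT_ASPECTS,
) -> pd.DataFrame:
    """Annual sums of the horizontal equivalent of ET0 (mm/yr) for a grid
    of slope inclinations and aspects.

    For multi-year weather the mean annual sum is reported.  The shared
    horizontal irradiance decomposition is computed once and re-projected
    for every slope/aspect combination.
    """
    lat = np.deg2rad(latitude_deg)
    lon = np.deg2rad(longitude_deg)
    split = subdaily_irradiance(weather, lat, lon)
    n_years = max(len(set(weather.index.year)), 1)
    out = {}
    for name, aspect_deg in aspects:
        col = []
        for inc in inclinations_deg:
            slope = solar.SlopeSpec(np.deg2rad(inc), np.deg2rad(aspect_deg))
            et0 = daily_et0(weather, lat, lon, slope, elevation, albedo, split=split)
            col.append(et0["ET0"].sum() / n_years)
        out[name] = col
    return pd.DataFrame(out, index=pd.Index(inclinations_deg, name="inclination_deg"))


# ---------------------------------------------------------------------------
# Stationary-climate drought replicates
# ---------------------------------------------------------------------------


def seasonal_fraction_profile(
    site: SiteConfig, weather_year: pd.DataFrame, n_photons: int = 5000, seed: int = 0
) -> pd.DataFrame:
    """Day-of-year radiation-fraction climatology from one simulated
    season, for re-use across replicate runs."""
    fr = radiation_fractions(site, weather_year, n_photons, seed)
    doy = pd.DatetimeIndex(weather_year.index).dayofyear
    prof = fr.assign(doy=doy).groupby("doy")[["f_R_v", "f_R_s"]].mean()
    return prof.reindex(range(1, 367)).ffill().bfill()


def drought_day_replicate(
    soil: SoilParams,
    spec,
    years: int,
    seed: int,
    fraction_profile: pd.DataFrame,
) -> pd.Series:
    """One stationary-climate replicate on flat terrain: synthetic weather,
    daily ET0 and the water balance; returns the daily FTSW series."""
    from .weather import generate_synthetic_weather

    weather = generate_synthetic_weather(spec, years, seed)
    lat = np.deg2rad(spec.latitude_deg)
    ra = np.asarray(solar.daily_extraterrestrial(lat, weather.index.dayofyear))
    rn = solar.net_radiation_slope(
        weather["tmin"], weather["tmax"], weather["rh"], weather["rglob"], ra
    )
    et0 = np.asarray(
        solar.et0_fao56(
            weather["tmin"],
            weather["tmax"],
            weather["tmean"],
            weather["rh"],
            weather["u2"],
            rn,
        ).et0
    )
    doy = weather.index.dayofyear
    f_r_v = fraction_profile["f_R_v"].to_numpy()[doy - 1]
    f_r_s = fraction_profile["f_R_s"].to_numpy()[doy - 1]
    calendar = cover_crop_calendar(weather.index, weather["tmin"].to_numpy())
    daily = run_water_balance(
        soil,
        weather.index,
        weather["precip"].to_numpy(),
        et0,
        f_r_v,
        f_r_s,
        calendar=calendar,
    )
    return daily["FTSW"]
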