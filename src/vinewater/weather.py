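"""Daily weather I/O, sub-daily radiation disaggregation and a seeded
stochastic weather generator.

The generator emulates a humid-temperate, summer-rainfall climate of the
middle-Rhine type: about 544 mm annual precipitation spread fairly evenly
over the year (July maximum near 60 mm, April minimum near 35 mm),
dominated by light events below 10 mm/day which contribute roughly two
thirds of the total, and a growing-season (April-September) reference
evapotranspiration around 600 mm.  Precipitation occurrence follows a
two-state Markov chain with gamma-distributed amounts; temperature is a
seasonal sinusoid with AR(1) noise; global radiation is the clear-sky
envelope scaled by a beta-distributed transmission that depends on wet/dry
state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solar import daily_extraterrestrial, extraterrestrial_radiation

#: canonical column names and their units
WEATHER_COLUMNS = {
    "tmin": "deg C",
    "tmax": "deg C",
    "tmean": "deg C",
    "rh": "%",
    "u2": "m s-1",
    "precip": "mm",
    "rglob": "MJ m-2 d-1",
}


def validate_weather(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a daily weather frame: required columns, physical ranges,
    calendar gaps (flagged in ``df.attrs['gaps']``)."""
    missing_cols = set(WEATHER_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"missing weather columns: {sorted(missing_cols)}")
    if not isinstance(df.index, pd.DatetimeIndex):
        raise ValueError("weather frame must be indexed by date")
    bad_rows = []
    if (df["tmin"] > df["tmax"]).any():
        bad_rows.append("tmin > tmax")
    if ((df["rh"] < 0) | (df["rh"] > 100)).any():
        bad_rows.append("rh outside [0, 100]")
    for col in ("precip", "u2", "rglob"):
        if (df[col] < 0).any():
            bad_rows.append(f"negative {col}")
    if bad_rows:
        raise ValueError("invalid weather values: " + "; ".join(bad_rows))
    gaps = pd.date_range(df.index[0], df.index[-1], freq="D").difference(df.index)
    df.attrs["gaps"] = list(gaps.date)
    return df


def read_daily_weather(path, sep: str | None = None, column_map: dict | None = None) -> pd.DataFrame:
    """Read a delimited-text daily weather series.

    ``sep=None`` sniffs comma vs semicolon.  ``column_map`` renames
    national-weather-service export headers onto the canonical names
    (date, tmin, tmax, tmean, rh, u2, precip, rglob).
    """
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = ";" if header.count(";") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    if "date" not in df.columns:
        raise ValueError("weather file must contain a 'date' column")
    try:
        df["date"] = pd.to_datetime(df["date"])
    except (ValueError, TypeError) as err:
        raise ValueError(f"unparsable dates in weather file: {err}") from err
    df = df.set_index("date").sort_index()
    return validate_weather(df)


def write_daily_weather(df: pd.DataFrame, path) -> None:
    """Write a weather frame back to CSV (lossless round-trip with
    :func:`read_daily_weather` for finite values)."""
    out = df.copy()
    out.index.name = "date"
    out.to_csv(path, float_format="%.17g")


def disaggregate_radiation(
    r_glob_daily: float,
    latitude: float,
    date,
    longitude: float = 0.0,
    freq: str = "30min",
) -> pd.Series:
    """Spread a daily global-radiation total (MJ m-2 d-1) over sub-daily
    instants proportionally to extraterrestrial irradiance.

    Returns W m-2 at each timestamp; the time integral recovers the daily
    total, values are zero at night and peak at solar noon.
    """
    if r_glob_daily < 0:
        raise ValueError("daily radiation must be non-negative")
    day = pd.Timestamp(date).normalize()
    times = pd.date_range(day, day + pd.Timedelta(days=1), freq=freq, inclusive="left")
    r0 = np.asarray(extraterrestrial_radiation(latitude, times, longitude=longitude))
    dt_h = (times[1] - times[0]).total_seconds() / 3600.0
    total_mj = np.sum(r0) * dt_h * 3600.0 / 1e6
    if total_mj <= 0:
        return pd.Series(np.zeros_like(r0), index=times)
    return pd.Series(r0 * (r_glob_daily / total_mj), index=times)


# ---------------------------------------------------------------------------
# Synthetic weather generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClimateSpec:
    """Parameters of the stochastic weather generator.

    Defaults are calibrated so that long runs reproduce the target climate
    normals: ~544 mm/yr precipitation with a July maximum and April
    minimum, about two thirds of it from days below 10 mm, and an
    April-September reference evapotranspiration near 600 mm on flat
    terrain.
    """

    latitude_deg: float = 49.98
    longitude_deg: float = 7.95
    #: monthly precipitation normals, mm (Jan..Dec); sum 544
    monthly_precip_mm: tuple = (40, 38, 40, 35, 48, 52, 60, 52, 45, 45, 45, 44)
    #: Markov persistence: P(wet | wet)
    p_wet_wet: float = 0.55
    #: long-run wet-day frequency
    wet_day_freq: float = 0.40
    #: gamma shape of wet-day amounts
    gamma_shape: float = 0.80
    temp_mean_c: float = 10.8
    temp_amplitude_c: float = 9.0
    #: day of year of the coldest day
    temp_phase_doy: float = 15.0
    temp_ar1: float = 0.70
    temp_sigma_c: float = 2.0
    #: mean diurnal range on dry / wet days
    diurnal_range_dry_c: float = 12.0
    diurnal_range_wet_c: float = 6.0
    rh_mean: float = 68.0
    rh_seasonal_amplitude: float = 9.0
    rh_wet_bonus: float = 10.0
    rh_sigma: float = 5.0
    wind_shape: float = 4.0
    wind_mean_ms: float = 2.7
    #: beta parameters of the atmospheric transmission (fraction of the
    #: 0.75 clear-sky ceiling) on dry and wet days
    transmission_dry: tuple = (8.0, 2.4)
    transmission_wet: tuple = (3.0, 6.5)
    clear_sky_fraction: float = 0.75


def generate_synthetic_weather(
    spec: ClimateSpec, years: int, seed: int
) -> pd.DataFrame:
    """Generate a reproducible daily weather series of ``years`` calendar
    years (starting 2001-01-01) from the climate specification."""
    if years < 1:
        raise ValueError("need at least one year")
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2001-01-01", periods=int(years * 365.25) + 1, freq="D")
    dates = dates[dates.year < 2001 + years]
    n = len(dates)
    doy = dates.dayofyear.to_numpy(dtype=float)
    month = dates.month.to_numpy() - 1

    # -- precipitation occurrence: two-state Markov chain
    p11 = spec.p_wet_wet
    pi_wet = spec.wet_day_freq
    p01 = pi_wet * (1.0 - p11) / (1.0 - pi_wet)
    wet = np.zeros(n, dtype=bool)
    u = rng.random(n)
    wet[0] = u[0] < pi_wet
    for i in range(1, n):
        wet[i] = u[i] < (p11 if wet[i - 1] else p01)

    # -- amounts: gamma, monthly mean scaled to the normals
    monthly = np.asarray(spec.monthly_precip_mm, dtype=float)
    days_in_month = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
    wet_mean = monthly / (days_in_month * pi_wet)  # mean wet-day amount
    scale = wet_mean[month] / spec.gamma_shape
    precip = np.where(wet, rng.gamma(spec.gamma_shape, 1.0, size=n) * scale, 0.0)

    # -- temperature: seasonal cycle + AR(1) noise
    season = -np.cos(2 * np.pi * (doy - spec.temp_phase_doy) / 365.25)
    tmean_clim = spec.temp_mean_c + spec.temp_amplitude_c * season
    noise = np.empty(n)
    eps = rng.normal(0.0, spec.temp_sigma_c, n)
    noise[0] = eps[0]
    for i in range(1, n):
        noise[i] = spec.temp_ar1 * noise[i - 1] + eps[i]
    tmean = tmean_clim + noise
    half_range = np.where(wet, spec.diurnal_range_wet_c, spec.diurnal_range_dry_c) / 2.0
    tmax = tmean + half_range
    tmin = tmean - half_range

    # -- humidity and wind
    rh_season = spec.rh_mean - spec.rh_seasonal_amplitude * season
    rh = rh_season + np.where(wet, spec.rh_wet_bonus, 0.0) + rng.normal(
        0, spec.rh_sigma, n
    )
    rh = np.clip(rh, 25.0, 100.0)
    u2 = rng.gamma(spec.wind_shape, spec.wind_mean_ms / spec.wind_shape, n)

    # -- radiation: clear-sky ceiling times beta transmission
    lat = np.deg2rad(spec.latitude_deg)
    ra = np.asarray(daily_extraterrestrial(lat, doy))
    a_d, b_d = spec.transmission_dry
    a_w, b_w = spec.transmission_wet
    trans = np.where(
        wet, rng.beta(a_w, b_w, n), rng.beta(a_d, b_d, n)
    )
    rglob = spec.clear_sky_fraction * trans * ra

    df = pd.DataFrame(
        {
            "tmin": tmin,
            "tmax": tmax,
            "tmean": tmean,
            "rh": rh,
            "u2": u2,
            "precip": precip,
            "rglob": rglob,
        },
        index=dates,
    )
    df.index.name = "date"
    return validate_weather(df)
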