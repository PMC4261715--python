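"""Daily two-reservoir vineyard soil-water bookkeeping.

The rooting profile is a single store characterised by its total
transpirable soil water (TTSW, mm); the fraction of transpirable soil water
FTSW = TSW/TTSW is the central soil-moisture state.  A sub-reservoir of
capacity ``TTSW_cc = TTSW(1 m) * f_cc`` is accessible to the cover crop
(rooting to about 1 m on the fraction ``f_cc`` of the area it occupies);
grapevine roots span the whole profile and extract from both
sub-reservoirs.  Daily fluxes (all in mm of horizontal equivalent):

* bare-soil evaporation via a two-stage model with a thin *skin layer* of
  capacity REW refilled first by rain, so small rain events evaporate at
  the energy-limited rate: ``E = K_e * f_R_s * ET0`` with ``K_e = K_r``,
  ``K_r = 1`` while the skin holds water and ``(TEW - De)/(TEW - REW)``
  afterwards;
* vine transpiration ``T_0_v = f_R_v * ET0`` scaled by the transpiration
  coefficient ``k_c_v`` (default 0.56) and the bilinear water-stress
  coefficient ``k_s`` with FTSW breakpoint ``p_FTSW`` (default 0.4);
* cover-crop evapotranspiration switching between bare-soil evaporation and
  transpiration through a frost-calendar ground-cover coefficient ``f_g``.

Rain exceeding storage capacity is lost (no distinction between surface
runoff and deep percolation); the daily budget closes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date, timedelta

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SoilParams:
    """Soil reservoir capacities and model coefficients (mm and
    dimensionless)."""

    ttsw: float
    ttsw_1m: float
    tew: float
    rew: float
    f_cc: float = 0.0
    p_ftsw: float = 0.4
    p_ftsw_cc: float = 0.4
    k_c_v: float = 0.56

    def __post_init__(self) -> None:
        if not 0 < self.rew < self.tew:
            raise ValueError("evaporable water must satisfy 0 < REW < TEW")
        if not 0 <= self.f_cc <= 1:
            raise ValueError("cover-crop fraction f_cc must lie in [0, 1]")
        if self.ttsw <= 0 or self.ttsw_1m <= 0:
            raise ValueError("TTSW and TTSW(1 m) must be positive")
        if self.ttsw_cc > self.ttsw + 1e-9:
            raise ValueError("TTSW_cc = TTSW(1 m) * f_cc must not exceed TTSW")
        if self.p_ftsw <= 0 or self.p_ftsw_cc <= 0:
            raise ValueError("stress thresholds must be positive")

    @property
    def ttsw_cc(self) -> float:
        """Capacity of the cover-crop sub-reservoir (mm)."""
        return self.ttsw_1m * self.f_cc

    @property
    def ttsw_r(self) -> float:
        """Capacity of the remaining (vine-only) sub-reservoir (mm)."""
        return self.ttsw - self.ttsw_cc


@dataclass
class SoilState:
    """Daily water stocks (mm): total and cover-crop transpirable water plus
    the depletions of the evaporation layer and its skin."""

    tsw: float
    tsw_cc: float
    de: float = 0.0
    de_skin: float = 0.0

    @classmethod
    def full(cls, params: SoilParams) -> "SoilState":
        """Winter-refilled initial state (reservoirs full, skin wet)."""
        return cls(tsw=params.ttsw, tsw_cc=params.ttsw_cc, de=0.0, de_skin=0.0)

    def ftsw(self, params: SoilParams) -> float:
        return self.tsw / params.ttsw

    def ftsw_cc(self, params: SoilParams) -> float:
        if params.ttsw_cc <= 0:
            return 1.0
        return self.tsw_cc / params.ttsw_cc

    @property
    def tsw_r(self) -> float:
        return self.tsw - self.tsw_cc


@dataclass(frozen=True)
class DailyFlux:
    """One day's evapotranspiration ledger (mm) and coefficients."""

    p: float
    e: float
    e_s: float
    et_a_cc: float
    t_0_v: float
    t_a_v: float
    et_a: float
    overflow: float
    k_e: float
    k_r: float
    k_s: float
    k_s_cc: float
    k_s_v_cc: float
    k_s_v_r: float
    f_g: float


# ---------------------------------------------------------------------------
# Elementary fluxes
# ---------------------------------------------------------------------------


def soil_evaporation_step(
    state: SoilState, params: SoilParams, p: float, frs_et0: float
) -> tuple[float, float, float, float]:
    """Bare-soil evaporation for one day.

    Rain refills the skin layer first, then the evaporation layer.  While
    the skin holds water evaporation proceeds at the energy-limited rate
    (``K_r = 1``); once it is dry the rate falls with the relative content
    of the evaporation layer.  Energy available at the soil surface is
    ``f_R_s * ET0``.

    Returns ``(E, new_de, new_de_skin, k_r)``.
    """
    if p < 0 or frs_et0 < 0:
        raise ValueError("precipitation and energy terms must be non-negative")
    de_skin = max(0.0, state.de_skin - p)
    de = max(0.0, state.de - p)
    if de_skin < params.rew:
        k_r = 1.0
    else:
        k_r = (params.tew - de) / (params.tew - params.rew)
        k_r = min(1.0, max(0.0, k_r))
    e = min(k_r * frs_et0, params.tew - de)
    e = max(0.0, e)
    return e, min(params.tew, de + e), min(params.rew, de_skin + e), k_r


def vineyard_soil_evaporation(e: float, f_cc: float) -> float:
    """Bare-soil evaporation of the vineyard: the cover-cropped area
    fraction does not evaporate as bare soil: ``E_s = E (1 - f_cc)``."""
    if not 0 <= f_cc <= 1:
        raise ValueError("f_cc must lie in [0, 1]")
    return e * (1.0 - f_cc)


def stress_coefficient(ftsw: float, p_ftsw: float) -> float:
    """Bilinear water-stress coefficient: 1 above the FTSW breakpoint,
    declining linearly to zero below it."""
    if p_ftsw <= 0:
        raise ValueError("p_FTSW must be positive")
    if ftsw <= p_ftsw:
        return max(0.0, ftsw) / p_ftsw
    return 1.0


def vine_transpiration(
    f_r_v: float, et0: float, k_s: float, k_c_v: float
) -> tuple[float, float]:
    """Potential and actual vine transpiration:
    ``T_0_v = f_R_v ET0`` and ``T_a_v = k_c_v k_s T_0_v``."""
    t_0_v = f_r_v * et0
    return t_0_v, k_c_v * k_s * t_0_v


def partition_extraction(
    state: SoilState, params: SoilParams, k_s: float
) -> tuple[float, float]:
    """Split the vine stress coefficient between the cover-crop and the
    remaining sub-reservoir, ``k_s = k_s_v_cc + k_s_v_r``.

    The four cases weigh the feedback of water stress appearing in the
    whole profile or in the individual sub-reservoirs: under overall stress
    extraction follows the cover-crop share of the remaining water; without
    stress it follows capacity shares, shifted towards whichever
    sub-reservoir still holds freely available water.
    """
    p = params.p_ftsw
    if params.ttsw_cc <= 0:
        return 0.0, k_s
    ftsw_cc = state.ftsw_cc(params)
    ftsw_r = state.tsw_r / params.ttsw_r if params.ttsw_r > 0 else 1.0
    if k_s < 1.0:
        k_cc = state.tsw_cc / (p * params.ttsw)
    elif ftsw_cc >= p and ftsw_r >= p:
        k_cc = params.ttsw_cc / params.ttsw
    elif ftsw_cc < p and ftsw_r >= p:
        k_cc = state.tsw_cc / (p * params.ttsw)
    else:
        # remaining reservoir stressed while the cover-crop one is not
        k_cc = 1.0 - state.tsw_r / (p * params.ttsw)
    k_cc = min(max(k_cc, 0.0), k_s)
    return k_cc, k_s - k_cc


def cover_crop_et(
    f_g: float, k_s_cc: float, frs_et0: float, e: float, f_cc: float
) -> float:
    """Cover-crop evapotranspiration:
    ``ET_a_cc = f_cc (f_g k_s_cc f_R_s ET0 + (1 - f_g) E)``."""
    if not 0 <= f_cc <= 1 or not 0 <= f_g <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if min(k_s_cc, frs_et0, e) < 0:
        raise ValueError("inputs must be non-negative")
    return f_cc * (f_g * k_s_cc * frs_et0 + (1.0 - f_g) * e)


# ---------------------------------------------------------------------------
# Cover-crop calendar
# ---------------------------------------------------------------------------

FROST_THRESHOLD_C = -4.0
INITIAL_STAGE_DAYS = 30
DEVELOPMENT_STAGE_DAYS = 50
#: Late spring frosts from this month on are ignored for the season start
_SPRING_FROST_CUTOFF_MONTH = 4


@dataclass
class CoverCropCalendar:
    """Season stage boundaries per year, derived from the frost calendar.

    The growing season starts 7 days before the last sub-threshold spring
    frost and ends 7 days after the first autumn frost; spring frosts in
    April or May are ignored so they cannot artificially retard the cover
    crop.  Stages: initial (30 d, dormant), development (50 d, ground cover
    ramps 0 to 1), mid-season (full cover), late season (dormant).
    """

    starts: dict = field(default_factory=dict)  # year -> date
    dev_end: dict = field(default_factory=dict)  # year -> date
    ends: dict = field(default_factory=dict)  # year -> date
    flagged_years: list = field(default_factory=list)

    def ground_cover(self, day: _date) -> float:
        """Ground-cover coefficient f_g for one calendar day."""
        year = day.year
        if year not in self.starts:
            return 0.0
        start = self.starts[year]
        mid_start = self.dev_end[year]
        end = self.ends[year]
        if day < start + timedelta(days=INITIAL_STAGE_DAYS) or day >= end:
            return 0.0
        if day >= mid_start:
            return 1.0
        ramp_start = start + timedelta(days=INITIAL_STAGE_DAYS)
        return (day - ramp_start).days / DEVELOPMENT_STAGE_DAYS


def cover_crop_calendar(
    dates, tmin, default_start_month_day=(3, 1), default_end_month_day=(12, 1)
) -> CoverCropCalendar:
    """Derive the cover-crop stage calendar from a daily Tmin series."""
    dates = pd.DatetimeIndex(dates)
    tmin = np.asarray(tmin, dtype=float)
    cal = CoverCropCalendar()
    for year in sorted(set(dates.year)):
        mask = dates.year == year
        d_y = dates[mask]
        t_y = tmin[mask]
        frost = t_y <= FROST_THRESHOLD_C
        spring = frost & (d_y.month < _SPRING_FROST_CUTOFF_MONTH)
        if spring.any():
            last = d_y[spring][-1].date()
            start = last - timedelta(days=7)
        else:
            start = _date(year, *default_start_month_day)
            cal.flagged_years.append(year)
        autumn = frost & (d_y.month >= 8)
        if autumn.any():
            end = d_y[autumn][0].date() + timedelta(days=7)
        else:
            end = _date(year, *default_end_month_day)
        cal.starts[year] = start
        cal.dev_end[year] = start + timedelta(
            days=INITIAL_STAGE_DAYS + DEVELOPMENT_STAGE_DAYS
        )
        cal.ends[year] = end
    return cal


def ground_cover(day: _date, cal: CoverCropCalendar) -> float:
    """Ground-cover coefficient for one day (functional form of
    :meth:`CoverCropCalendar.ground_cover`)."""
    return cal.ground_cover(day)


# ---------------------------------------------------------------------------
# Daily step and season driver
# ---------------------------------------------------------------------------


def daily_step(
    state: SoilState,
    params: SoilParams,
    p: float,
    et0: float,
    f_r_v: float,
    f_r_s: float,
    f_g: float,
) -> tuple[DailyFlux, SoilState]:
    """Advance the water balance by one day.

    All demand terms are computed from the start-of-day state; rain and
    fluxes are then applied simultaneously.  If a sub-reservoir cannot
    supply its demand the corresponding fluxes are scaled down to the
    available water; cover-crop reservoir overflow cascades into the
    remaining reservoir before any water is counted as lost.  The returned
    ledger satisfies ``TSW' - TSW = P - ET_a - overflow`` exactly.
    """
    if any(np.isnan(v) for v in (p, et0, f_r_v, f_r_s)):
        raise ValueError("NaN in weather or radiation inputs")
    frs_et0 = f_r_s * et0

    e, de_new, de_skin_new, k_r = soil_evaporation_step(state, params, p, frs_et0)
    e_s = vineyard_soil_evaporation(e, params.f_cc)

    ftsw = state.ftsw(params)
    k_s = stress_coefficient(ftsw, params.p_ftsw)
    t_0_v, t_a_v = vine_transpiration(f_r_v, et0, k_s, params.k_c_v)

    k_s_cc = stress_coefficient(state.ftsw_cc(params), params.p_ftsw_cc)
    et_a_cc = cover_crop_et(f_g, k_s_cc, frs_et0, e, params.f_cc)

    k_s_v_cc, k_s_v_r = partition_extraction(state, params, k_s)
    ext_cc = k_s_v_cc * params.k_c_v * t_0_v
    ext_r = k_s_v_r * params.k_c_v * t_0_v

    # --- cover-crop sub-reservoir
    avail_cc = state.tsw_cc + p * params.f_cc
    out_cc = et_a_cc + ext_cc
    if out_cc > avail_cc > 0 or (avail_cc <= 0 and out_cc > 0):
        scale = max(avail_cc, 0.0) / out_cc
        et_a_cc *= scale
        ext_cc *= scale
        out_cc = et_a_cc + ext_cc
    cc_spill = max(0.0, avail_cc - out_cc - params.ttsw_cc)
    tsw_cc_new = max(0.0, min(params.ttsw_cc, avail_cc - out_cc))

    # --- remaining sub-reservoir (receives the cover-crop spill)
    avail_r = state.tsw_r + p * (1.0 - params.f_cc) + cc_spill
    out_r = e_s + ext_r
    if out_r > avail_r > 0 or (avail_r <= 0 and out_r > 0):
        scale = max(avail_r, 0.0) / out_r
        e_s *= scale
        ext_r *= scale
        out_r = e_s + ext_r
    overflow = max(0.0, avail_r - out_r - params.ttsw_r)
    tsw_r_new = max(0.0, min(params.ttsw_r, avail_r - out_r))

    t_a_v = ext_cc + ext_r
    et_a = t_a_v + et_a_cc + e_s
    new_state = SoilState(
        tsw=tsw_cc_new + tsw_r_new,
        tsw_cc=tsw_cc_new,
        de=de_new,
        de_skin=de_skin_new,
    )
    flux = DailyFlux(
        p=p,
        e=e,
        e_s=e_s,
        et_a_cc=et_a_cc,
        t_0_v=t_0_v,
        t_a_v=t_a_v,
        et_a=et_a,
        overflow=overflow,
        k_e=k_r,
        k_r=k_r,
        k_s=k_s,
        k_s_cc=k_s_cc,
        k_s_v_cc=k_s_v_cc,
        k_s_v_r=k_s_v_r,
        f_g=f_g,
    )
    return flux, new_state


def run_water_balance(
    params: SoilParams,
    dates,
    precipitation,
    et0,
    f_r_v,
    f_r_s,
    calendar: CoverCropCalendar | None = None,
    initial: SoilState | None = None,
) -> pd.DataFrame:
    """Run the daily water balance over aligned series; returns one row per
    day with states, fluxes and coefficients.

    Raises on calendar gaps in ``dates``.
    """
    dates = pd.DatetimeIndex(dates)
    gaps = pd.date_range(dates[0], dates[-1], freq="D").difference(dates)
    if len(gaps):
        raise ValueError(
            "weather series has gaps: "
            f"{[d.strftime('%Y-%m-%d') for d in gaps[:5]]} ..."
        )

    p_arr = np.asarray(precipitation, dtype=float)
    et0_arr = np.asarray(et0, dtype=float)
    frv = np.asarray(f_r_v, dtype=float)
    frs = np.asarray(f_r_s, dtype=float)
    n = len(dates)
    if not (len(p_arr) == len(et0_arr) == len(frv) == len(frs) == n):
        raise ValueError("input series must be aligned to the date index")

    state = initial if initial is not None else SoilState.full(params)
    rows = []
    for i in range(n):
        day = dates[i].date()
        f_g = calendar.ground_cover(day) if calendar is not None else 0.0
        try:
            flux, state = daily_step(
                state, params, p_arr[i], et0_arr[i], frv[i], frs[i], f_g
            )
        except ValueError as err:
            raise ValueError(f"{day}: {err}") from err
        rows.append(
            {
                "P": flux.p,
                "ET0": et0_arr[i],
                "f_R_v": frv[i],
                "f_R_s": frs[i],
                "E": flux.e,
                "E_s": flux.e_s,
                "ET_a_cc": flux.et_a_cc,
                "T_0_v": flux.t_0_v,
                "T_a_v": flux.t_a_v,
                "ET_a": flux.et_a,
                "overflow": flux.overflow,
                "K_r": flux.k_r,
                "k_s": flux.k_s,
                "k_s_cc": flux.k_s_cc,
                "k_s_v_cc": flux.k_s_v_cc,
                "k_s_v_r": flux.k_s_v_r,
                "f_g": flux.f_g,
                "TSW": state.tsw,
                "TSW_cc": state.tsw_cc,
                "FTSW": state.ftsw(params),
                "FTSW_cc": state.ftsw_cc(params),
                "De": state.de,
                "De_skin": state.de_skin,
            }
        )
    return pd.DataFrame(rows).set_index(pd.DatetimeIndex(dates))
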