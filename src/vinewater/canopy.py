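"""Row-canopy geometry, porosity law and thermal-time phenology.

The grapevine row is represented as a cuboid: foliage of width ``L`` and
height ``H`` raised ``S`` metres above the soil (the stem zone), repeating
with row distance ``D`` and considered infinite along the row.  Light
attenuation inside the cuboid follows a Beer-Lambert law parameterised by
the perpendicular porosity ``p0`` of a vertical foliage wall: a photon
travelling a path of length ``x`` through foliage survives with probability

    p(x) = p0 ** (x / L),

i.e. an extinction coefficient ``k = -ln(p0) / L``, assuming leaf area is
homogeneously dispersed in the cuboid.  ``p0`` and ``L`` are both directly
measurable in the field, which is the point of this parameterisation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class CanopyGeometry:
    """Cuboid row-canopy description.

    Attributes
    ----------
    row_distance : float
        Distance D between row axes (m).
    height : float
        Foliage height H (m), excluding the stem zone.
    width : float
        Foliage width L (m).
    stem_height : float
        Height S of the foliage base above the soil surface (m).
    porosity : float
        Perpendicular porosity p0 of a vertical foliage wall.
    row_azimuth : float
        Azimuth of the row direction, radians, south-zero convention.
    """

    row_distance: float
    height: float
    width: float
    stem_height: float = 0.0
    porosity: float = 0.25
    row_azimuth: float = 0.0

    @property
    def top(self) -> float:
        """Height of the canopy top above the soil (m)."""
        return self.stem_height + self.height

    @property
    def extinction(self) -> float:
        """Extinction coefficient k = -ln(p0)/L (m-1); inf for p0 = 0."""
        if self.porosity <= 0.0:
            return np.inf
        if self.porosity >= 1.0:
            return 0.0
        return -np.log(self.porosity) / self.width

    @property
    def has_foliage(self) -> bool:
        return self.height > 0.0 and self.width > 0.0 and self.porosity < 1.0


def validate_geometry(geom: CanopyGeometry) -> CanopyGeometry:
    """Check the geometric invariants, returning the geometry unchanged.

    Raises ``ValueError`` naming the violated constraint.
    """
    if geom.row_distance <= 0:
        raise ValueError("row distance D must be positive")
    if geom.height > 0 and not 0 < geom.width <= geom.row_distance:
        raise ValueError("foliage width must satisfy 0 < L <= D")
    if geom.height < 0 or geom.width < 0:
        raise ValueError("canopy dimensions must be non-negative")
    if geom.stem_height < 0:
        raise ValueError("stem height S must be non-negative")
    if not 0.0 <= geom.porosity <= 1.0:
        raise ValueError("porosity p0 must lie in [0, 1]")
    return geom


def porosity_at_distance(p0: float, width: float, x) -> np.ndarray | float:
    """Porosity (non-interception probability) for a travel distance ``x``
    through the foliage: ``p(x) = p0 ** (x / L)``.

    Satisfies p(0) = 1, p(L) = p0 and the semigroup property
    p(x1 + x2) = p(x1) p(x2).
    """
    if width <= 0:
        raise ValueError("foliage width must be positive")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("porosity p0 must lie in [0, 1]")
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("travel distance must be non-negative")
    if p0 == 0.0:
        out = np.where(x_arr > 0, 0.0, 1.0)
    else:
        out = np.exp(np.log(p0) * x_arr / width)
    if np.isscalar(x):
        return float(out)
    return out


@dataclass(frozen=True)
class PhenologyParams:
    """Thermal-time thresholds (deg C day above base temperature, cumulative
    from 1 January) controlling the piecewise-linear seasonal development of
    the canopy.

    Between budburst and hedging, height and width grow linearly from zero
    to their targets while porosity falls linearly from 1 to ``p0_min``;
    hedging then holds the geometry constant.  During leaf abscission the
    porosity ramps linearly back to 1.
    """

    tt_budburst: float = 120.0
    tt_hedging: float = 600.0
    tt_abscission_start: float = 1600.0
    tt_abscission_end: float = 1900.0
    base_temperature: float = 10.0

    def __post_init__(self) -> None:
        seq = (
            self.tt_budburst,
            self.tt_hedging,
            self.tt_abscission_start,
            self.tt_abscission_end,
        )
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(
                "phenology thresholds must be strictly ordered: "
                "budburst < hedging < abscission start < abscission end"
            )


def thermal_time(tmean, dates, base_temperature: float = 10.0) -> np.ndarray:
    """Cumulative growing degree days above the base temperature, reset at
    the start of each calendar year."""
    tmean = np.asarray(tmean, dtype=float)
    years = np.asarray([d.year for d in dates])
    gdd = np.maximum(tmean - base_temperature, 0.0)
    out = np.empty_like(gdd)
    for year in np.unique(years):
        mask = years == year
        out[mask] = np.cumsum(gdd[mask])
    return out


def develop_canopy(
    tt_cumulative,
    params: PhenologyParams,
    target: CanopyGeometry,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seasonal canopy state (H, L, p0 arrays) from cumulative thermal time.

    ``target`` holds the fully developed (post-hedging) geometry; its
    ``porosity`` field is the seasonal minimum.  Outside the foliated period
    H = L = 0 and p0 = 1.
    """
    validate_geometry(target)
    tt = np.asarray(tt_cumulative, dtype=float)

    grow = np.clip(
        (tt - params.tt_budburst) / (params.tt_hedging - params.tt_budburst), 0.0, 1.0
    )
    fall = np.clip(
        (tt - params.tt_abscission_start)
        / (params.tt_abscission_end - params.tt_abscission_start),
        0.0,
        1.0,
    )
    # leaf fall thins the canopy (p0 -> 1) and shrinks its envelope so the
    # state is continuous in thermal time throughout the season
    height = target.height * grow * (1.0 - fall)
    width = target.width * grow * (1.0 - fall)
    p0 = 1.0 - (1.0 - target.porosity) * grow
    p0 = p0 + (1.0 - p0) * fall
    done = tt >= params.tt_abscission_end
    height = np.where(done, 0.0, height)
    width = np.where(done, 0.0, width)
    p0 = np.where(done, 1.0, p0)
    return height, width, p0


def canopy_state_on(
    geom: CanopyGeometry, height: float, width: float, p0: float
) -> CanopyGeometry:
    """Geometry with seasonal dimensions substituted in."""
    return replace(geom, height=float(height), width=float(width), porosity=float(p0))
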