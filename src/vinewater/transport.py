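"""Monte Carlo short-wave radiation transport in the periodic row-canopy
domain, plus the opaque-face geometric comparator model.

Domain
------
Photons are tracked in a vineyard-local frame attached to the slope plane:
``x`` is the cross-row coordinate (periodic with the row distance ``D``),
``y`` runs along the row (translation invariant, rows are infinite) and
``z`` is the distance from the soil surface along the slope normal.  The
foliage cuboid occupies ``0 <= x < L`` and ``S <= z < S + H`` in every
period.  Directions are full 3-D unit vectors.

Physics
-------
Inside the cuboid the free path to the next foliage interaction is drawn
from an exponential distribution with extinction ``k = -ln(p0)/L`` (the
turbid-medium equivalent of the porosity law ``p(x) = p0**(x/L)``).  On
interaction a photon is absorbed with probability ``alpha_v = 1 - rho_l -
tau``; otherwise it scatters into the backward hemisphere with probability
``rho_l/(rho_l + tau)`` and forward with ``tau/(rho_l + tau)``, with
cosine-distributed directions about the incident axis.  The soil absorbs
with ``alpha_s = 1 - rho_s`` and reflects Lambertian otherwise.  Photon
fates (absorbed by vine, absorbed by soil, escaped to the sky) are counted
exactly, so the three fractions always sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .canopy import CanopyGeometry, validate_geometry
from .solar import SlopeSpec, SolarPosition

FATE_PENDING = 0
FATE_VINE = 1
FATE_SOIL = 2
FATE_ESCAPED = 3

#: Analog-simulation bounce cap; survival of 50 scattering events has
#: negligible probability for any physical leaf/soil optics.
BOUNCE_CAP = 50


@dataclass(frozen=True)
class OpticalProps:
    """Single-photon short-wave optical properties.

    Defaults are typical broadband values for green foliage and a dry
    loam/stony vineyard soil.
    """

    leaf_reflectivity: float = 0.20
    leaf_transmittance: float = 0.10
    soil_albedo: float = 0.18

    def __post_init__(self) -> None:
        for name, v in (
            ("leaf_reflectivity", self.leaf_reflectivity),
            ("leaf_transmittance", self.leaf_transmittance),
            ("soil_albedo", self.soil_albedo),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.leaf_reflectivity + self.leaf_transmittance > 1.0:
            raise ValueError("leaf reflectivity + transmittance must not exceed 1")

    @property
    def alpha_v(self) -> float:
        """Foliage absorptance for single photons."""
        return 1.0 - self.leaf_reflectivity - self.leaf_transmittance

    @property
    def alpha_s(self) -> float:
        """Soil absorptance for single photons."""
        return 1.0 - self.soil_albedo


BLACK_OPTICS = OpticalProps(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class LocalSunDirection:
    """Sun direction in the vineyard-local frame.

    ``vector`` points *towards* the sun with components ordered
    (along-row, cross-row, slope-normal).  ``gamma_v`` is the vineyard
    solar azimuth: the angle between the sun's projection onto the slope
    plane and the row axis, so the cross-row spread of shadows scales with
    ``|sin(gamma_v)|``.
    """

    vector: np.ndarray
    local_zenith: float
    gamma_v: float

    @property
    def above_horizon(self) -> bool:
        return self.vector[2] > 0.0


def _wrap_angle(a):
    return (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi


def local_sun_angles(
    theta_z, gamma_s, slope: SlopeSpec, row_azimuth: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised rotation of global sun angles into the vineyard-local
    frame; returns ``(local_zenith, gamma_v)`` arrays.

    A flat vineyard is the exact identity: ``local_zenith = theta_z`` and
    ``gamma_v = gamma_s - row_azimuth`` bit-for-bit.
    """
    theta_z = np.asarray(theta_z, dtype=float)
    gamma_s = np.asarray(gamma_s, dtype=float)
    if slope.beta == 0.0:
        return theta_z, _wrap_angle(gamma_s - row_azimuth)

    sin_t = np.sin(theta_z)
    s = np.stack(
        [sin_t * np.cos(gamma_s), sin_t * np.sin(gamma_s), np.cos(theta_z)], axis=-1
    )
    e1, e2, e3 = _local_basis(slope, row_azimuth)
    s1 = s @ e1
    s2 = s @ e2
    s3 = s @ e3
    return np.arccos(np.clip(s3, -1.0, 1.0)), np.arctan2(s2, s1)


def _local_basis(slope: SlopeSpec, row_azimuth: float):
    """Orthonormal vineyard basis in the global (south, west, up) frame:
    e1 along the rows (projected into the slope plane), e3 the slope
    normal, e2 = e3 x e1 cross-row."""
    n = np.array(
        [
            np.sin(slope.beta) * np.cos(slope.aspect),
            np.sin(slope.beta) * np.sin(slope.aspect),
            np.cos(slope.beta),
        ]
    )
    r_h = np.array([np.cos(row_azimuth), np.sin(row_azimuth), 0.0])
    e1 = r_h - np.dot(r_h, n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2, n


def rotate_to_vineyard_frame(
    sun: SolarPosition, slope: SlopeSpec, row_azimuth: float
) -> LocalSunDirection:
    """Rigid rotation of the sun direction into the vineyard-local frame."""
    theta_l, gamma_v = local_sun_angles(sun.zenith, sun.azimuth, slope, row_azimuth)
    theta_l = float(theta_l)
    gamma_v = float(gamma_v)
    sin_t = np.sin(theta_l)
    vec = np.array(
        [sin_t * np.cos(gamma_v), sin_t * np.sin(gamma_v), np.cos(theta_l)]
    )
    return LocalSunDirection(vector=vec, local_zenith=theta_l, gamma_v=gamma_v)


@dataclass(frozen=True)
class InterceptionFractions:
    """Photon-fate fractions from a Monte Carlo run.

    ``a_v`` and ``a_s`` are the fractions absorbed by the vines and the
    soil; ``escaped`` is the fraction reflected back to the sky (the
    simulated vineyard albedo for that source).  As photon-count ratios the
    three sum to one exactly.
    """

    a_v: float
    a_s: float
    escaped: float
    n: int
    se_v: float
    se_s: float
    below_horizon: bool = False

    @classmethod
    def from_counts(cls, n_v: int, n_s: int, n_esc: int) -> "InterceptionFractions":
        n = n_v + n_s + n_esc
        a_v, a_s = n_v / n, n_s / n
        return cls(
            a_v=a_v,
            a_s=a_s,
            escaped=n_esc / n,
            n=n,
            se_v=float(np.sqrt(a_v * (1 - a_v) / n)),
            se_s=float(np.sqrt(a_s * (1 - a_s) / n)),
        )


_ZERO_FRACTIONS = InterceptionFractions(0.0, 0.0, 0.0, 0, 0.0, 0.0, below_horizon=True)


def _cosine_about_axis(axis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample directions cosine-distributed about unit axis vectors (m, 3)."""
    m = axis.shape[0]
    u = rng.random(m)
    phi = rng.random(m) * 2.0 * np.pi
    mu = np.sqrt(u)
    s = np.sqrt(1.0 - u)
    # orthonormal frame about each axis
    helper = np.where(
        (np.abs(axis[:, 2]) < 0.9)[:, None],
        np.array([0.0, 0.0, 1.0]),
        np.array([1.0, 0.0, 0.0]),
    )
    b = np.cross(axis, helper)
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    c = np.cross(axis, b)
    return (
        mu[:, None] * axis
        + s[:, None] * (np.cos(phi)[:, None] * b + np.sin(phi)[:, None] * c)
    )


def _trace_batch(
    geom: CanopyGeometry,
    optics: OpticalProps,
    x0: np.ndarray,
    directions: np.ndarray,
    rng: np.random.Generator,
    bounce_cap: int = BOUNCE_CAP,
) -> np.ndarray:
    """Trace a batch of photons; returns the fate code per photon.

    ``x0`` are cross-row entry coordinates on the top plane, ``directions``
    (n, 3) unit vectors ordered (cross-row, along-row, normal) with a
    negative normal component (downward into the domain).
    """
    n = x0.shape[0]
    D = geom.row_distance
    L = geom.width if geom.has_foliage else 0.0
    S = geom.stem_height
    top = geom.top if geom.has_foliage else 0.0
    k = geom.extinction if geom.has_foliage else 0.0
    alpha_v, alpha_s = optics.alpha_v, optics.alpha_s
    rho_l, tau = optics.leaf_reflectivity, optics.leaf_transmittance
    p_back = rho_l / (rho_l + tau) if (rho_l + tau) > 0 else 1.0

    eps = 1e-9 * max(D, top, 1.0)
    x = np.mod(x0.astype(float), D)
    # start a hair below the top plane so entries over the row footprint are
    # immediately "inside" the foliage
    z = np.full(n, top - 0.5 * eps if top > 0 else 0.0)
    d = directions.astype(float).copy()
    fate = np.full(n, FATE_PENDING, dtype=np.int8)
    bounces = np.zeros(n, dtype=np.int16)

    for _ in range(100000):
        pending = np.flatnonzero(fate == FATE_PENDING)
        if pending.size == 0:
            break
        xi, zi, di = x[pending], z[pending], d[pending]
        dx, dz = di[:, 0], di[:, 2]

        # 1) escape through the open sky
        esc = (dz > 0) & (zi >= top - eps)
        # degenerate perfectly-horizontal rays that can never interact
        esc |= (np.abs(dz) < 1e-14) & (np.abs(dx) < 1e-14)
        fate[pending[esc]] = FATE_ESCAPED

        # 2) soil interaction
        soil = ~esc & (zi <= eps)
        if np.any(soil):
            si = pending[soil]
            u = rng.random(si.size)
            absorbed = u < alpha_s
            fate[si[absorbed]] = FATE_SOIL
            refl = si[~absorbed]
            if refl.size:
                d[refl] = _cosine_about_axis(
                    np.broadcast_to(np.array([0.0, 0.0, 1.0]), (refl.size, 3)).copy(),
                    rng,
                )
                z[refl] = 2.0 * eps  # lift off the surface so the soil test clears
                bounces[refl] += 1
                over = refl[bounces[refl] > bounce_cap]
                fate[over] = FATE_SOIL

        # 3) march the remaining photons one segment
        move = pending[np.flatnonzero((~esc) & (~soil) & (fate[pending] == FATE_PENDING))]
        if move.size == 0:
            continue
        xm, zm = x[move], z[move]
        dm = d[move]
        dxm, dzm = dm[:, 0], dm[:, 2]

        inside = (
            (L > 0.0) & (xm < L) & (zm >= S) & (zm < top)
        )

        t_next = np.full(move.size, np.inf)
        # z-plane crossings
        for zp in ((0.0, S, top) if top > 0 else (0.0,)):
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (zp - zm) / dzm
            valid = np.isfinite(t) & (t > eps)
            t_next = np.where(valid, np.minimum(t_next, t), t_next)
        # x-plane (foliage wall) crossings, periodic
        if L > 0.0:
            fwd = dxm > 1e-14
            bwd = dxm < -1e-14
            xb_f = np.where(xm < L - eps, L, D)
            t_f = (xb_f - xm) / np.where(fwd, dxm, 1.0)
            t_next = np.where(fwd & (t_f > eps), np.minimum(t_next, t_f), t_next)
            xb_b = np.where(xm > L + eps, L, 0.0)
            t_b = (xb_b - xm) / np.where(bwd, dxm, 1.0)
            t_next = np.where(bwd & (t_b > eps), np.minimum(t_next, t_b), t_next)

        # free path inside the foliage
        interact = np.zeros(move.size, dtype=bool)
        if np.any(inside):
            if np.isinf(k):
                path = np.zeros(int(np.count_nonzero(inside)))
            else:
                path = rng.exponential(1.0 / k, size=int(np.count_nonzero(inside)))
            s_full = np.full(move.size, np.inf)
            s_full[inside] = path
            interact = inside & (s_full < t_next)
            t_step = np.where(interact, s_full, t_next + eps)
        else:
            t_step = t_next + eps

        # photons with no finite boundary ahead escape upward
        runaway = ~interact & ~np.isfinite(t_next)
        fate[move[runaway]] = FATE_ESCAPED

        ok = ~runaway
        mo = move[ok]
        step = t_step[ok]
        x[mo] = np.mod(xm[ok] + dm[ok, 0] * step, D)
        z[mo] = zm[ok] + dm[ok, 2] * step

        # foliage interaction outcomes
        hit = move[interact]
        if hit.size:
            u = rng.random(hit.size)
            absorbed = u < alpha_v
            fate[hit[absorbed]] = FATE_VINE
            scat = hit[~absorbed]
            if scat.size:
                back = rng.random(scat.size) < p_back
                axis = d[scat] * np.where(back, -1.0, 1.0)[:, None]
                d[scat] = _cosine_about_axis(axis, rng)
                bounces[scat] += 1
                over = scat[bounces[scat] > bounce_cap]
                fate[over] = FATE_VINE
    else:  # pragma: no cover - safety net
        stuck = fate == FATE_PENDING
        fate[stuck] = np.where(z[stuck] < S, FATE_SOIL, FATE_VINE)
    return fate


def trace_photon(
    geom: CanopyGeometry,
    optics: OpticalProps,
    direction: np.ndarray,
    entry_x: float,
    rng: np.random.Generator,
) -> str:
    """Trace a single photon entering the top plane at cross-row position
    ``entry_x`` with the given (cross-row, along-row, normal) unit travel
    direction; returns ``'absorbed_vine'``, ``'absorbed_soil'`` or
    ``'escaped'``."""
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    if direction[2] >= 0:
        raise ValueError("direction must point downward into the domain")
    if not 0 <= entry_x < geom.row_distance:
        raise ValueError("entry_x must lie within one row period [0, D)")
    fate = _trace_batch(geom, optics, np.array([entry_x]), direction[None, :], rng)[0]
    return {FATE_VINE: "absorbed_vine", FATE_SOIL: "absorbed_soil", FATE_ESCAPED: "escaped"}[
        int(fate)
    ]


def _sun_travel_directions(sun_local: LocalSunDirection, n: int) -> np.ndarray:
    """Replicate the downward travel direction for a direct-beam source."""
    s = sun_local.vector
    # vector is (along-row, cross-row, normal) pointing to the sun; photon
    # travel is the reverse, ordered (cross-row, along-row, normal)
    d = np.array([-s[1], -s[0], -s[2]])
    return np.broadcast_to(d, (n, 3)).copy()


def simulate_direct(
    geom: CanopyGeometry,
    optics: OpticalProps,
    sun_local: LocalSunDirection,
    n: int,
    seed_or_rng,
) -> InterceptionFractions:
    """Monte Carlo interception/absorption fractions for a direct beam."""
    if n < 1:
        raise ValueError("photon count must be >= 1")
    validate_geometry(geom)
    if not sun_local.above_horizon:
        return _ZERO_FRACTIONS
    rng = np.random.default_rng(seed_or_rng)
    x0 = rng.uniform(0.0, geom.row_distance, n)
    fate = _trace_batch(geom, optics, x0, _sun_travel_directions(sun_local, n), rng)
    return InterceptionFractions.from_counts(
        int(np.count_nonzero(fate == FATE_VINE)),
        int(np.count_nonzero(fate == FATE_SOIL)),
        int(np.count_nonzero(fate == FATE_ESCAPED)),
    )


def simulate_diffuse(
    geom: CanopyGeometry,
    optics: OpticalProps,
    n: int,
    seed_or_rng,
) -> InterceptionFractions:
    """Monte Carlo fractions for an isotropic sky source, sampled
    cosine-weighted over the hemisphere above the vineyard plane."""
    if n < 1:
        raise ValueError("photon count must be >= 1")
    validate_geometry(geom)
    rng = np.random.default_rng(seed_or_rng)
    x0 = rng.uniform(0.0, geom.row_distance, n)
    u = rng.random(n)
    phi = rng.random(n) * 2.0 * np.pi
    sin_t = np.sqrt(1.0 - u)
    dirs = np.stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), -np.sqrt(u)], axis=1
    )
    fate = _trace_batch(geom, optics, x0, dirs, rng)
    return InterceptionFractions.from_counts(
        int(np.count_nonzero(fate == FATE_VINE)),
        int(np.count_nonzero(fate == FATE_SOIL)),
        int(np.count_nonzero(fate == FATE_ESCAPED)),
    )


# ---------------------------------------------------------------------------
# Radiation partitioning per timestep and per day
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RadiationPartition:
    """Absorbed radiation components for one timestep (W m-2 of vineyard
    plane) and the resulting partition fractions."""

    r_v: float
    r_s: float
    r_vy: float
    f_r_v: float
    f_r_s: float
    albedo_vy: float
    defined: bool = True


def partition_timestep(
    direct: InterceptionFractions,
    diffuse: InterceptionFractions,
    beam_poa: float,
    diffuse_poa: float,
) -> RadiationPartition:
    """Combine absorbed fractions with slope-plane irradiance components.

    ``beam_poa`` carries the directional (beam + circumsolar) irradiance,
    ``diffuse_poa`` the isotropic sky and ground-reflected part.
    """
    r_glob = beam_poa + diffuse_poa
    r_v = direct.a_v * beam_poa + diffuse.a_v * diffuse_poa
    r_s = direct.a_s * beam_poa + diffuse.a_s * diffuse_poa
    r_vy = r_v + r_s
    if r_vy <= 0.0:
        return RadiationPartition(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, defined=False)
    return RadiationPartition(
        r_v=r_v,
        r_s=r_s,
        r_vy=r_vy,
        f_r_v=r_v / r_vy,
        f_r_s=r_s / r_vy,
        albedo_vy=1.0 - r_vy / r_glob if r_glob > 0 else 0.0,
    )


def daily_fractions(
    partitions,
    fallback: tuple[float, float] | None = None,
) -> tuple[float, float, bool]:
    """Energy-weighted daily fractions (f_R_v, f_R_s, defined).

    Fractions are ratios of summed absorbed radiation, i.e. weighted by the
    absorbed energy of each timestep.  On an all-dark day the ``fallback``
    (typically the previous day's fractions) is returned with
    ``defined=False``.
    """
    if len(partitions) == 0:
        raise ValueError("need at least one timestep")
    r_v = sum(p.r_v for p in partitions)
    r_vy = sum(p.r_vy for p in partitions)
    if r_vy <= 0.0:
        f_v, f_s = fallback if fallback is not None else (0.0, 1.0)
        return f_v, f_s, False
    return r_v / r_vy, 1.0 - r_v / r_vy, True


# ---------------------------------------------------------------------------
# Opaque-face analytic comparator
# ---------------------------------------------------------------------------


def riou_analytic(
    geom: CanopyGeometry,
    local_zenith: float,
    gamma_v: float,
    porosity: float | None = None,
    n_grid: int = 4001,
) -> float:
    """Direct-beam interception fraction of the antecedent geometric
    row-canopy model, which treats the horizontal faces of the foliage
    cuboid as opaque.

    Beams striking the canopy footprint from above are fully intercepted by
    the opaque top face; beams entering the inter-row gap attenuate along
    their within-foliage path according to the porosity law.  The gap term
    therefore equals the expected Monte Carlo interception exactly, and the
    whole difference between the two models is the opaque-face treatment of
    the footprint - which is what makes this model overestimate
    interception, increasingly so at high porosity.  Deterministic
    (midpoint-rule average over entry positions).
    """
    if local_zenith >= np.pi / 2:
        raise ValueError("sun must be above the local horizon")
    if not geom.has_foliage:
        return 0.0
    p0 = geom.porosity if porosity is None else porosity
    D, L, H = geom.row_distance, geom.width, geom.height

    sin_t = np.sin(local_zenith)
    cross = sin_t * abs(np.sin(gamma_v))
    m = np.tan(local_zenith) * abs(np.sin(gamma_v))
    w = H * m
    if w <= 0.0:
        return L / D

    # gap entry positions (midpoint rule over [L, D))
    x = L + (np.arange(n_grid) + 0.5) * (D - L) / n_grid
    x_end = x + w

    def foliage_measure(t):
        return np.floor(t / D) * L + np.minimum(np.mod(t, D), L)

    c = foliage_measure(x_end) - foliage_measure(x)
    if p0 <= 0.0:
        transmitted = np.where(c > 0, 0.0, 1.0)
    else:
        # path length through foliage = c / (sin(theta) |sin(gamma_v)|)
        transmitted = p0 ** (c / (L * cross))
    gap_interception = float(np.mean(1.0 - transmitted)) * (D - L) / D
    return min(1.0, L / D + gap_interception)


# ---------------------------------------------------------------------------
# Interception lookup table
# ---------------------------------------------------------------------------

_DEFAULT_ZENITH_GRID_DEG = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 85.0)
_DEFAULT_GAMMA_GRID_DEG = (0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0)


def _direction_from_angles(theta: float, gamma_v: float) -> LocalSunDirection:
    sin_t = np.sin(theta)
    return LocalSunDirection(
        vector=np.array([sin_t * np.cos(gamma_v), sin_t * np.sin(gamma_v), np.cos(theta)]),
        local_zenith=theta,
        gamma_v=gamma_v,
    )


@dataclass
class InterceptionTable:
    """Absorbed-fraction lookup over a (local zenith, vineyard azimuth)
    grid, plus diffuse-sky scalars, for one frozen canopy state.

    The direct grid covers ``gamma_v`` in [0, pi/2]; queries are folded
    into that quadrant using the mirror symmetry of the geometry.  Bilinear
    interpolation between nodes.
    """

    zenith_grid: np.ndarray
    gamma_grid: np.ndarray
    a_v: np.ndarray
    a_s: np.ndarray
    se_v: np.ndarray
    a_dif_v: float
    a_dif_s: float
    n_photons: int
    seed: int
    meta: dict = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        geom: CanopyGeometry,
        optics: OpticalProps,
        n: int = 20000,
        seed: int = 0,
        zenith_grid_deg=_DEFAULT_ZENITH_GRID_DEG,
        gamma_grid_deg=_DEFAULT_GAMMA_GRID_DEG,
    ) -> "InterceptionTable":
        zg = np.deg2rad(np.asarray(zenith_grid_deg, dtype=float))
        gg = np.deg2rad(np.asarray(gamma_grid_deg, dtype=float))
        nz, ng = zg.size, gg.size
        a_v = np.zeros((nz, ng))
        a_s = np.zeros((nz, ng))
        se_v = np.zeros((nz, ng))
        meta = {
            "D": geom.row_distance,
            "H": geom.height,
            "L": geom.width,
            "S": geom.stem_height,
            "p0": geom.porosity,
        }
        if not geom.has_foliage:
            # bare vineyard: every photon strikes the soil once; reflected
            # photons escape, so the absorbed fraction is exactly alpha_s
            a_s[:] = optics.alpha_s
            return cls(zg, gg, a_v, a_s, se_v, 0.0, optics.alpha_s, n, seed, meta)

        rng = np.random.default_rng(seed)
        for i, th in enumerate(zg):
            for j, gv in enumerate(gg):
                fr = simulate_direct(geom, optics, _direction_from_angles(th, gv), n, rng)
                a_v[i, j], a_s[i, j], se_v[i, j] = fr.a_v, fr.a_s, fr.se_v
        dif = simulate_diffuse(geom, optics, n, rng)
        return cls(zg, gg, a_v, a_s, se_v, dif.a_v, dif.a_s, n, seed, meta)

    def _fold_gamma(self, gamma_v):
        g = np.abs(np.mod(np.asarray(gamma_v, dtype=float), np.pi))
        return np.minimum(g, np.pi - g)

    def query(self, local_zenith, gamma_v) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear interpolation of (a_v, a_s) at arbitrary sun angles;
        zenith queries beyond the grid edge clamp to the edge row."""
        th = np.clip(
            np.asarray(local_zenith, dtype=float),
            self.zenith_grid[0],
            self.zenith_grid[-1],
        )
        ga = np.clip(self._fold_gamma(gamma_v), self.gamma_grid[0], self.gamma_grid[-1])

        iz = np.clip(np.searchsorted(self.zenith_grid, th) - 1, 0, self.zenith_grid.size - 2)
        ig = np.clip(np.searchsorted(self.gamma_grid, ga) - 1, 0, self.gamma_grid.size - 2)
        z0, z1 = self.zenith_grid[iz], self.zenith_grid[iz + 1]
        g0, g1 = self.gamma_grid[ig], self.gamma_grid[ig + 1]
        wz = np.where(z1 > z0, (th - z0) / (z1 - z0), 0.0)
        wg = np.where(g1 > g0, (ga - g0) / (g1 - g0), 0.0)

        def interp(grid):
            return (
                grid[iz, ig] * (1 - wz) * (1 - wg)
                + grid[iz + 1, ig] * wz * (1 - wg)
                + grid[iz, ig + 1] * (1 - wz) * wg
                + grid[iz + 1, ig + 1] * wz * wg
            )

        return interp(self.a_v), interp(self.a_s)

    def to_frame(self) -> pd.DataFrame:
        """Columnar text representation (angles in degrees)."""
        rows = []
        for i, th in enumerate(self.zenith_grid):
            for j, gv in enumerate(self.gamma_grid):
                rows.append(
                    {
                        "zenith_deg": np.rad2deg(th),
                        "gamma_v_deg": np.rad2deg(gv),
                        "a_v": self.a_v[i, j],
                        "a_s": self.a_s[i, j],
                        "se_v": self.se_v[i, j],
                        "n": self.n_photons,
                        "seed": self.seed,
                        "a_dif_v": self.a_dif_v,
                        "a_dif_s": self.a_dif_s,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "InterceptionTable":
        df = pd.read_csv(path)
        zg = np.deg2rad(np.unique(df["zenith_deg"].to_numpy()))
        gg = np.deg2rad(np.unique(df["gamma_v_deg"].to_numpy()))
        shape = (zg.size, gg.size)
        return cls(
            zenith_grid=zg,
            gamma_grid=gg,
            a_v=df["a_v"].to_numpy().reshape(shape),
            a_s=df["a_s"].to_numpy().reshape(shape),
            se_v=df["se_v"].to_numpy().reshape(shape),
            a_dif_v=float(df["a_dif_v"].iloc[0]),
            a_dif_s=float(df["a_dif_s"].iloc[0]),
            n_photons=int(df["n"].iloc[0]),
            seed=int(df["seed"].iloc[0]),
        )


def build_interception_table(
    geom: CanopyGeometry,
    optics: OpticalProps,
    n: int = 20000,
    seed: int = 0,
    **kwargs,
) -> InterceptionTable:
    """Convenience wrapper around :meth:`InterceptionTable.build`."""
    return InterceptionTable.build(geom, optics, n=n, seed=seed, **kwargs)
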