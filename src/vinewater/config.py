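"""Site configuration: one vineyard's location, terrain, canopy, soil and
management bundle, loadable from a YAML file.

Three fixtures ship with the package for the middle-Rhine steep-slope
vineyards used throughout the documentation: ``EF`` (35 degree slope,
85 mm TTSW, wide rows), ``BU`` (27 degrees, 115 mm, tilled alternate rows)
and ``WI`` (15 degrees, 160 mm, deep loam).  Azimuth angles follow the
south-zero convention: east of south negative, west of south positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .canopy import CanopyGeometry, PhenologyParams, validate_geometry
from .solar import SlopeSpec
from .transport import OpticalProps
from .waterbalance import SoilParams


@dataclass(frozen=True)
class SiteConfig:
    """One vineyard: geometry + soil + management + location."""

    name: str
    latitude_deg: float
    longitude_deg: float
    elevation_m: float
    slope: SlopeSpec
    canopy: CanopyGeometry  # fully developed (post-hedging) state
    phenology: PhenologyParams
    soil: SoilParams
    optics: OpticalProps = OpticalProps()
    ground_albedo: float = 0.20
    k_c_v_measured: float | None = None

    @property
    def latitude(self) -> float:
        return np.deg2rad(self.latitude_deg)

    @property
    def longitude(self) -> float:
        return np.deg2rad(self.longitude_deg)


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ValueError(f"site config missing key '{key}' in section '{context}'")
    return mapping[key]


def site_config_from_dict(cfg: dict) -> SiteConfig:
    """Build and validate a :class:`SiteConfig` from a parsed mapping,
    naming the offending key on constraint violations."""
    canopy_cfg = _require(cfg, "canopy", "root")
    soil_cfg = _require(cfg, "soil", "root")
    phen_cfg = cfg.get("phenology", {})
    optics_cfg = cfg.get("optics", {})

    slope = SlopeSpec(
        beta=np.deg2rad(float(cfg.get("slope_deg", 0.0))),
        aspect=np.deg2rad(float(cfg.get("aspect_deg", 0.0))),
    )
    geom = validate_geometry(
        CanopyGeometry(
            row_distance=float(_require(canopy_cfg, "row_distance_m", "canopy")),
            height=float(_require(canopy_cfg, "height_m", "canopy")),
            width=float(_require(canopy_cfg, "width_m", "canopy")),
            stem_height=float(canopy_cfg.get("stem_height_m", 0.6)),
            porosity=float(_require(canopy_cfg, "porosity_min", "canopy")),
            row_azimuth=np.deg2rad(float(cfg.get("row_azimuth_deg", cfg.get("aspect_deg", 0.0)))),
        )
    )
    phenology = PhenologyParams(
        tt_budburst=float(phen_cfg.get("tt_budburst", 120.0)),
        tt_hedging=float(phen_cfg.get("tt_hedging", 600.0)),
        tt_abscission_start=float(phen_cfg.get("tt_abscission_start", 1600.0)),
        tt_abscission_end=float(phen_cfg.get("tt_abscission_end", 1900.0)),
        base_temperature=float(phen_cfg.get("base_temperature_c", 10.0)),
    )
    soil = SoilParams(
        ttsw=float(_require(soil_cfg, "ttsw_mm", "soil")),
        ttsw_1m=float(_require(soil_cfg, "ttsw_1m_mm", "soil")),
        tew=float(_require(soil_cfg, "tew_mm", "soil")),
        rew=float(_require(soil_cfg, "rew_mm", "soil")),
        f_cc=float(soil_cfg.get("f_cc", 0.0)),
        p_ftsw=float(soil_cfg.get("p_ftsw", 0.4)),
        p_ftsw_cc=float(soil_cfg.get("p_ftsw_cc", 0.4)),
        k_c_v=float(soil_cfg.get("k_c_v", 0.56)),
    )
    optics = OpticalProps(
        leaf_reflectivity=float(optics_cfg.get("leaf_reflectivity", 0.20)),
        leaf_transmittance=float(optics_cfg.get("leaf_transmittance", 0.10)),
        soil_albedo=float(optics_cfg.get("soil_albedo", 0.18)),
    )
    measured = cfg.get("measured", {})
    return SiteConfig(
        name=str(cfg.get("name", "site")),
        latitude_deg=float(_require(cfg, "latitude_deg", "root")),
        longitude_deg=float(_require(cfg, "longitude_deg", "root")),
        elevation_m=float(cfg.get("elevation_m", 100.0)),
        slope=slope,
        canopy=geom,
        phenology=phenology,
        soil=soil,
        optics=optics,
        ground_albedo=float(cfg.get("ground_albedo", 0.20)),
        k_c_v_measured=(
            float(measured["k_c_v_ratio"]) if "k_c_v_ratio" in measured else None
        ),
    )


def load_site_config(path_or_name) -> SiteConfig:
    """Load a site configuration from a YAML file, or one of the bundled
    fixtures by name ('EF', 'BU', 'WI')."""
    name = str(path_or_name)
    if name.upper() in BUNDLED_SITES:
        ref = resources.files("vinewater").joinpath(f"sites/{name.lower()}.yaml")
        cfg = yaml.safe_load(ref.read_text())
    else:
        with open(path_or_name) as fh:
            cfg = yaml.safe_load(fh)
    return site_config_from_dict(cfg)


BUNDLED_SITES = ("EF", "BU", "WI")


def mean_transpiration_coefficient(sites=BUNDLED_SITES) -> float:
    """Unweighted mean of the per-site measured ratios of actual to
    potential vine transpiration under non-limiting water - the model's
    grapevine transpiration coefficient k_c_v."""
    ratios = [load_site_config(s).k_c_v_measured for s in sites]
    if any(r is None for r in ratios):
        raise ValueError("all sites need a measured k_c_v ratio")
    return float(np.mean(ratios))
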