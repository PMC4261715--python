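"""Monte Carlo photon transport: conservation, oracle equivalence,
rotation identities, the analytic comparator and the lookup table."""

import numpy as np
import pytest
from scipy import integrate

from vinewater.canopy import CanopyGeometry
from vinewater.solar import SlopeSpec, SolarPosition
from vinewater.transport import (
    BLACK_OPTICS,
    InterceptionTable,
    OpticalProps,
    _direction_from_angles,
    daily_fractions,
    local_sun_angles,
    partition_timestep,
    riou_analytic,
    rotate_to_vineyard_frame,
    simulate_diffuse,
    simulate_direct,
    trace_photon,
)

NARROW_ROW_GEOM = CanopyGeometry(row_distance=1.6, height=1.1, width=0.4, stem_height=0.8, porosity=0.25)


def shadow_fraction_oracle(geom, theta, gamma_v):
    """Closed-form hedgerow shadow fraction for a black opaque canopy."""
    w = geom.height * np.tan(theta) * abs(np.sin(gamma_v))
    return min(1.0, (geom.width + w) / geom.row_distance)


class TestRotation:
    def test_flat_is_exact_identity(self):
        sun = SolarPosition(0.8, 0.3)
        local = rotate_to_vineyard_frame(sun, SlopeSpec(0.0, 1.0), row_azimuth=0.1)
        assert local.local_zenith == 0.8
        assert local.gamma_v == pytest.approx(0.2)

    def test_zenith_sun_local_zenith_equals_slope(self):
        beta = np.deg2rad(27.0)
        local = rotate_to_vineyard_frame(
            SolarPosition(0.0, 0.0), SlopeSpec(beta, 0.5), row_azimuth=0.5
        )
        assert local.local_zenith == pytest.approx(beta, abs=1e-12)

    def test_rotation_preserves_norm(self, rng):
        for _ in range(20):
            sun = SolarPosition(rng.uniform(0, np.pi / 2), rng.uniform(-np.pi, np.pi))
            slope = SlopeSpec(rng.uniform(0, 0.6), rng.uniform(-np.pi, np.pi))
            local = rotate_to_vineyard_frame(sun, slope, rng.uniform(-np.pi, np.pi))
            assert abs(np.linalg.norm(local.vector) - 1.0) < 1e-12

    def test_normal_incidence_maps_to_local_zenith_zero(self):
        beta, aspect = np.deg2rad(30.0), np.deg2rad(10.0)
        local = rotate_to_vineyard_frame(
            SolarPosition(beta, aspect), SlopeSpec(beta, aspect), row_azimuth=0.7
        )
        assert local.local_zenith == pytest.approx(0.0, abs=1e-9)

    def test_vectorized_matches_scalar(self, rng):
        slope = SlopeSpec(0.4, -0.3)
        thetas = rng.uniform(0, 1.5, 10)
        gammas = rng.uniform(-3, 3, 10)
        tl, gv = local_sun_angles(thetas, gammas, slope, 0.2)
        for i in range(10):
            local = rotate_to_vineyard_frame(
                SolarPosition(thetas[i], gammas[i]), slope, 0.2
            )
            assert tl[i] == pytest.approx(local.local_zenith)
            assert gv[i] == pytest.approx(local.gamma_v)


class TestTracePhoton:
    def test_opaque_black_full_cover_always_vine(self, rng):
        geom = CanopyGeometry(1.0, 1.0, 1.0, 0.0, porosity=0.0)
        fates = {
            trace_photon(geom, BLACK_OPTICS, np.array([0.1, 0.1, -1.0]) / np.linalg.norm([0.1, 0.1, -1.0]), 0.5, rng)
            for _ in range(50)
        }
        assert fates == {"absorbed_vine"}

    def test_no_canopy_black_soil_always_soil(self, rng):
        geom = CanopyGeometry(2.0, 0.0, 0.0, porosity=1.0)
        fates = {
            trace_photon(geom, OpticalProps(0, 0, 0.0), np.array([0.0, 0.0, -1.0]), 1.0, rng)
            for _ in range(50)
        }
        assert fates == {"absorbed_soil"}

    def test_no_canopy_mirror_soil_always_escapes(self, rng):
        geom = CanopyGeometry(2.0, 0.0, 0.0, porosity=1.0)
        fates = {
            trace_photon(geom, OpticalProps(0, 0, 1.0), np.array([0.0, 0.0, -1.0]), 0.3, rng)
            for _ in range(50)
        }
        assert fates == {"escaped"}

    def test_non_unit_direction_rejected(self, rng):
        geom = CanopyGeometry(2.0, 1.0, 0.4)
        with pytest.raises(ValueError, match="unit"):
            trace_photon(geom, BLACK_OPTICS, np.array([0.0, 0.0, -2.0]), 0.5, rng)


class TestSimulateDirect:
    def test_counts_partition_unity_exactly(self):
        fr = simulate_direct(
            NARROW_ROW_GEOM, OpticalProps(), _direction_from_angles(0.7, 0.9), 5000, 3
        )
        assert fr.a_v + fr.a_s + fr.escaped == 1.0

    def test_reproducible_for_fixed_seed(self):
        a = simulate_direct(NARROW_ROW_GEOM, OpticalProps(), _direction_from_angles(0.7, 0.9), 2000, 42)
        b = simulate_direct(NARROW_ROW_GEOM, OpticalProps(), _direction_from_angles(0.7, 0.9), 2000, 42)
        assert a == b

    def test_sun_below_local_horizon_flagged_zero(self):
        fr = simulate_direct(
            NARROW_ROW_GEOM, OpticalProps(), _direction_from_angles(np.pi / 2 + 0.1, 0.0), 100, 0
        )
        assert fr.below_horizon and fr.a_v == 0.0

    def test_matches_shadow_oracle_for_black_opaque(self, rng):
        """Black opaque hedgerow, S = 0: interception equals the
        closed-form shadow fraction within Monte Carlo error."""
        geom = CanopyGeometry(2.5, 1.0, 0.4, 0.0, porosity=0.0)
        for _ in range(5):
            theta = rng.uniform(0.1, 1.4)
            gamma_v = rng.uniform(-np.pi, np.pi)
            fr = simulate_direct(geom, BLACK_OPTICS, _direction_from_angles(theta, gamma_v), 40000, rng)
            oracle = shadow_fraction_oracle(geom, theta, gamma_v)
            assert fr.a_v == pytest.approx(oracle, abs=max(3 * fr.se_v, 1e-3))

    def test_energy_conservation_all_absorbing(self, rng):
        """With black leaves and soil nothing escapes from a downward beam."""
        fr = simulate_direct(
            CanopyGeometry(1.6, 1.1, 0.4, 0.8, 0.5),
            OpticalProps(0, 0, 0),
            _direction_from_angles(0.8, 1.0),
            20000,
            rng,
        )
        assert fr.escaped == 0.0


class TestSimulateDiffuse:
    def test_limits(self, rng):
        bare = CanopyGeometry(2.0, 0.0, 0.0, porosity=1.0)
        assert simulate_diffuse(bare, BLACK_OPTICS, 2000, rng).a_v == 0.0
        full = CanopyGeometry(1.0, 1.0, 1.0, 0.0, porosity=0.0)
        assert simulate_diffuse(full, BLACK_OPTICS, 2000, rng).a_v == 1.0

    def test_matches_hemisphere_quadrature_oracle(self):
        """Black opaque row: cosine-weighted sky integral of the shadow
        fraction, evaluated by deterministic 2-D quadrature."""
        geom = CanopyGeometry(2.0, 1.0, 0.5, 0.0, porosity=0.0)

        def integrand(theta, phi):
            return shadow_fraction_oracle(geom, theta, phi) * np.cos(theta) * np.sin(theta)

        val, _ = integrate.dblquad(
            integrand, 0, np.pi / 2, 0, np.pi / 2, epsabs=1e-6
        )
        oracle = val * 4 / np.pi  # four symmetric azimuth quadrants over pi

        fr = simulate_diffuse(geom, BLACK_OPTICS, 200000, 7)
        assert fr.a_v == pytest.approx(oracle, abs=3 * fr.se_v + 1e-3)


class TestStandardErrorScaling:
    def test_se_shrinks_as_root_n(self):
        sun = _direction_from_angles(0.8, 0.7)
        estimates = {
            n: [
                simulate_direct(NARROW_ROW_GEOM, BLACK_OPTICS, sun, n, seed).a_v
                for seed in range(12)
            ]
            for n in (1000, 16000)
        }
        sd_small = np.std(estimates[1000])
        sd_big = np.std(estimates[16000])
        # 16x the photons -> 4x smaller spread (loose factor-2 band)
        assert sd_big < sd_small / 2


class TestRiouAnalytic:
    def test_zenith_sun_opaque_gives_width_ratio(self):
        geom = CanopyGeometry(2.5, 1.0, 0.4, 0.0, porosity=0.0)
        assert riou_analytic(geom, 0.0, 0.0) == pytest.approx(0.4 / 2.5)

    def test_opaque_matches_shadow_formula(self, rng):
        geom = CanopyGeometry(2.5, 1.0, 0.4, 0.0, porosity=0.0)
        for _ in range(10):
            theta = rng.uniform(0.1, 1.4)
            gv = rng.uniform(-np.pi, np.pi)
            assert riou_analytic(geom, theta, gv) == pytest.approx(
                shadow_fraction_oracle(geom, theta, gv), abs=1e-3
            )

    def test_overestimates_porous_interception(self, rng):
        """The opaque-face treatment never intercepts less than the
        Monte Carlo porous canopy."""
        for _ in range(6):
            theta = rng.uniform(0.2, 1.3)
            gv = rng.uniform(-np.pi, np.pi)
            fr = simulate_direct(NARROW_ROW_GEOM, BLACK_OPTICS, _direction_from_angles(theta, gv), 30000, rng)
            assert riou_analytic(NARROW_ROW_GEOM, theta, gv) >= fr.a_v - 3 * fr.se_v


class TestPartitionAndDailyFractions:
    def test_dark_timestep_flagged(self):
        direct = simulate_direct(NARROW_ROW_GEOM, OpticalProps(), _direction_from_angles(0.5, 0.5), 1000, 0)
        diffuse = simulate_diffuse(NARROW_ROW_GEOM, OpticalProps(), 1000, 1)
        part = partition_timestep(direct, diffuse, 0.0, 0.0)
        assert not part.defined and part.r_vy == 0.0

    def test_conservation_r_v_plus_r_s(self):
        direct = simulate_direct(NARROW_ROW_GEOM, OpticalProps(), _direction_from_angles(0.5, 0.5), 2000, 0)
        diffuse = simulate_diffuse(NARROW_ROW_GEOM, OpticalProps(), 2000, 1)
        part = partition_timestep(direct, diffuse, 420.0, 130.0)
        assert part.r_v + part.r_s == pytest.approx(part.r_vy, abs=1e-9)
        assert part.f_r_v + part.f_r_s == pytest.approx(1.0, abs=1e-12)

    def test_single_timestep_day(self):
        direct = simulate_direct(NARROW_ROW_GEOM, OpticalProps(), _direction_from_angles(0.5, 0.5), 2000, 0)
        diffuse = simulate_diffuse(NARROW_ROW_GEOM, OpticalProps(), 2000, 1)
        part = partition_timestep(direct, diffuse, 300.0, 100.0)
        f_v, f_s, defined = daily_fractions([part])
        assert defined and f_v == pytest.approx(part.f_r_v)

    def test_equal_energy_steps_average_fractions(self):
        from vinewater.transport import RadiationPartition

        p1 = RadiationPartition(30.0, 70.0, 100.0, 0.3, 0.7, 0.1)
        p2 = RadiationPartition(50.0, 50.0, 100.0, 0.5, 0.5, 0.1)
        f_v, _, _ = daily_fractions([p1, p2])
        assert f_v == pytest.approx(0.4)

    def test_all_dark_day_uses_fallback(self):
        from vinewater.transport import RadiationPartition

        dark = RadiationPartition(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, defined=False)
        f_v, f_s, defined = daily_fractions([dark], fallback=(0.31, 0.69))
        assert (f_v, f_s) == (0.31, 0.69) and not defined


@pytest.fixture(scope="module")
def table():
    return InterceptionTable.build(NARROW_ROW_GEOM, OpticalProps(), n=4000, seed=9)


class TestInterceptionTable:

    def test_grid_node_query_is_exact(self, table):
        i, j = 3, 2
        a_v, a_s = table.query(table.zenith_grid[i], table.gamma_grid[j])
        assert float(a_v) == table.a_v[i, j]
        assert float(a_s) == table.a_s[i, j]

    def test_mirror_symmetry_of_queries(self, table):
        for gv in (0.3, 1.0):
            plus = table.query(0.6, gv)
            minus = table.query(0.6, -gv)
            assert float(plus[0]) == pytest.approx(float(minus[0]), abs=1e-12)
            assert float(plus[1]) == pytest.approx(float(minus[1]), abs=1e-12)

    def test_interpolated_query_close_to_fresh_simulation(self, table):
        theta, gv = 0.62, 0.40
        a_v, _ = table.query(theta, gv)
        fresh = simulate_direct(NARROW_ROW_GEOM, OpticalProps(), _direction_from_angles(theta, gv), 40000, 5)
        assert float(a_v) == pytest.approx(fresh.a_v, abs=3 * fresh.se_v + 0.02)

    def test_roundtrip_through_csv(self, table, tmp_path):
        path = tmp_path / "table.csv"
        table.to_csv(path)
        back = InterceptionTable.from_csv(path)
        np.testing.assert_allclose(back.a_v, table.a_v)
        assert back.a_dif_v == pytest.approx(table.a_dif_v)

    def test_bare_canopy_uses_exact_soil_absorptance(self):
        bare = CanopyGeometry(2.0, 0.0, 0.0, porosity=1.0)
        table = InterceptionTable.build(bare, OpticalProps(0.2, 0.1, 0.18), n=100, seed=0)
        a_v, a_s = table.query(0.4, 0.2)
        assert float(a_v) == 0.0
        assert float(a_s) == pytest.approx(0.82)
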