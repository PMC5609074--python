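"""Closed-form inversion: round-trips, composition identity, localization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoloc import (
    HeatSource,
    NoSourceDetectedError,
    NoiseSpec,
    ObservationPair,
    TissueParams,
    depth_from_temps,
    estimate_source,
    generate_synthetic_thermogram,
    intensity_from_temps,
    localize_from_thermogram,
    radius_depth_relation,
    radius_from_intensity,
    surface_profile,
    surface_temperature,
)

FOUR_PI = 4 * math.pi


def observation_from_forward(source, tissue, a):
    return ObservationPair(
        T_max=surface_temperature(source, tissue, 0.0),
        T_a=surface_temperature(source, tissue, a),
        a=a, T_env=tissue.T_env_C)


class TestDepthFromTemps:
    def test_forward_fixture_recovers_depth(self, tissue, point_fixture_source):
        obs = observation_from_forward(point_fixture_source, tissue, 0.01)
        assert depth_from_temps(obs) == pytest.approx(0.014, rel=1e-12)

    def test_half_height_reading_gives_depth_equal_offset(self):
        obs = ObservationPair(T_max=30.0, T_a=28.5, a=0.013, T_env=27.0)
        assert depth_from_temps(obs) == pytest.approx(0.013, rel=1e-15)

    def test_clinical_temperatures_hand_value(self):
        # ambient 20, local 33.4, peak 35.2 at 1 cm offset
        obs = ObservationPair(T_max=35.2, T_a=33.4, a=0.01, T_env=20.0)
        assert depth_from_temps(obs) == pytest.approx(
            0.01 * math.sqrt(13.4 / 1.8), rel=1e-12)  # ~0.0273 m

    @pytest.mark.parametrize("kwargs", [
        dict(T_max=30.0, T_a=30.0, a=0.01, T_env=27.0),   # T_max == T_a
        dict(T_max=30.0, T_a=27.0, a=0.01, T_env=27.0),   # T_a == T_env
        dict(T_max=30.0, T_a=29.0, a=0.0, T_env=27.0),    # zero offset
        dict(T_max=29.0, T_a=29.5, a=0.01, T_env=27.0),   # inverted pair
    ])
    def test_degenerate_observations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ObservationPair(**kwargs)


class TestIntensityFromTemps:
    def test_forward_fixture_recovers_intensity(self, tissue,
                                                point_fixture_source):
        obs = observation_from_forward(point_fixture_source, tissue, 0.01)
        assert intensity_from_temps(obs, tissue.h0) == pytest.approx(
            0.1, rel=1e-12)

    def test_clinical_temperatures_hand_value(self):
        obs = ObservationPair(T_max=35.2, T_a=33.4, a=0.01, T_env=20.0)
        expected = FOUR_PI * 8.77 * 1e-4 * 13.4 * 15.2 / 1.8  # ~1.247 W
        assert intensity_from_temps(obs, 8.77) == pytest.approx(
            expected, rel=1e-12)

    def test_offset_invariance_on_noiseless_data(self, tissue):
        """Different reading offsets give the identical estimates."""
        source = HeatSource(Q=0.25, d=0.018, R=0.004)
        results = []
        for a in (0.005, 0.01, 0.02, 0.05):
            obs = observation_from_forward(source, tissue, a)
            results.append((depth_from_temps(obs),
                            intensity_from_temps(obs, tissue.h0)))
        d_effs, qs = zip(*results)
        np.testing.assert_allclose(d_effs, source.d_eff, rtol=1e-10)
        np.testing.assert_allclose(qs, source.Q, rtol=1e-10)

    def test_nonpositive_h0_rejected(self):
        obs = ObservationPair(T_max=30.0, T_a=29.0, a=0.01, T_env=27.0)
        with pytest.raises(ValueError):
            intensity_from_temps(obs, 0.0)


class TestRadiusFormulas:
    def test_identity_case(self):
        assert radius_from_intensity(700e-6, 700, 1e-6) == pytest.approx(1.0)

    def test_zero_intensity(self):
        assert radius_from_intensity(0.0, 700, 1e-6) == 0.0

    def test_hand_value(self):
        assert radius_from_intensity(0.1, 700, 1e-6) == pytest.approx(
            (0.1 / 7e-4) ** (1 / 3), rel=1e-12)

    def test_cube_root_scaling(self):
        assert radius_from_intensity(8 * 0.05, 700) == pytest.approx(
            2 * radius_from_intensity(0.05, 700), rel=1e-12)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            radius_from_intensity(0.1, 0.0)
        with pytest.raises(ValueError):
            radius_from_intensity(0.1, 700, 0.0)

    def test_ambient_reading_gives_zero_radius(self):
        assert radius_depth_relation(27.0, 27.0, 0.01, 0.014, 8.77, 700) == 0.0

    def test_below_ambient_rejected(self):
        with pytest.raises(ValueError):
            radius_depth_relation(26.0, 27.0, 0.01, 0.014, 8.77, 700)

    def test_composition_identity_on_fixture(self, tissue,
                                             point_fixture_source):
        """Intensity-free radius == cube root of (Eq.18 intensity / q_m A_t)."""
        obs = observation_from_forward(point_fixture_source, tissue, 0.01)
        d_eff = depth_from_temps(obs)
        q = intensity_from_temps(obs, tissue.h0)
        r_direct = radius_depth_relation(obs.T_a, obs.T_env, obs.a, d_eff,
                                         tissue.h0, tissue.q_m)
        r_composed = radius_from_intensity(q, tissue.q_m, 1e-6)
        assert r_direct == pytest.approx(r_composed, rel=1e-14)
        # the implied intensity round-trips: R^3 q_m 1e-6 == Q
        assert r_direct**3 * tissue.q_m * 1e-6 == pytest.approx(0.1, rel=1e-10)


class TestRoundTripProperties:
    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(q=st.floats(0.01, 1.0), d=st.floats(2e-3, 0.03),
           a=st.floats(5e-3, 0.1))
    def test_point_source_round_trip(self, q, d, a):
        """Measurable configurations (elevations well above float
        cancellation on the ~27 degC baseline) invert to 1e-10."""
        tissue = TissueParams()
        source = HeatSource(Q=q, d=d, R=0.0)
        obs = observation_from_forward(source, tissue, a)
        assert abs(depth_from_temps(obs) - d) <= 1e-10 * d
        assert abs(intensity_from_temps(obs, tissue.h0) - q) <= 1e-10 * q

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(q=st.floats(1e-3, 1.0), d=st.floats(2e-3, 0.04),
           r=st.floats(1e-4, 0.02), a=st.floats(1e-3, 0.1))
    def test_sphere_returns_effective_depth_never_geometric(self, q, d, r, a):
        tissue = TissueParams()
        obs = observation_from_forward(HeatSource(Q=q, d=d, R=r), tissue, a)
        d_est = depth_from_temps(obs)
        assert d_est == pytest.approx(d + r, rel=1e-10)
        assert d_est > d  # never the geometric depth

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(q=st.floats(1e-3, 1.0), d=st.floats(2e-3, 0.05),
           a=st.floats(1e-3, 0.1))
    def test_intensity_free_radius_equals_composition(self, q, d, a):
        tissue = TissueParams()
        obs = observation_from_forward(HeatSource(Q=q, d=d), tissue, a)
        d_eff = depth_from_temps(obs)
        lhs = radius_depth_relation(obs.T_a, obs.T_env, obs.a, d_eff,
                                    tissue.h0, tissue.q_m)
        rhs = radius_from_intensity(
            intensity_from_temps(obs, tissue.h0), tissue.q_m, 1e-6)
        assert lhs == pytest.approx(rhs, rel=1e-13)


class TestLocalizeFromThermogram:
    def test_noiseless_grid_round_trip_machine_precision(
            self, tissue, point_fixture_source):
        grid = generate_synthetic_thermogram(point_fixture_source, tissue,
                                             (41, 41), 0.005)
        result = localize_from_thermogram(grid, tissue)
        assert result.d_eff == pytest.approx(0.014, rel=1e-12)
        assert result.Q == pytest.approx(0.1, rel=1e-12)

    def test_noiseless_profile_round_trip(self, tissue):
        source = HeatSource(Q=0.2, d=0.01, R=0.005)
        profile = surface_profile(source, tissue, np.linspace(-0.05, 0.05, 41))
        result = localize_from_thermogram(profile, tissue)
        assert result.d_eff == pytest.approx(source.d_eff, rel=1e-10)
        assert result.Q == pytest.approx(source.Q, rel=1e-10)

    def test_radius_method_flag_and_decomposition(self, tissue,
                                                  point_fixture_source):
        grid = generate_synthetic_thermogram(point_fixture_source, tissue,
                                             (41, 41), 0.005)
        for method in ("eq-intensity-free", "from-intensity"):
            result = localize_from_thermogram(grid, tissue,
                                              radius_method=method)
            assert result.method_flags["radius_method"] == method
            assert result.d == max(result.d_eff - result.R, 0.0)

    def test_constant_grid_raises_no_source(self, tissue):
        grid = generate_synthetic_thermogram(
            HeatSource(Q=0.0, d=0.01), tissue, (21, 21), 0.005)
        with pytest.raises(NoSourceDetectedError):
            localize_from_thermogram(grid, tissue)

    def test_boundary_peak_flagged(self, tissue):
        grid = generate_synthetic_thermogram(
            HeatSource(Q=0.1, d=0.014), tissue, (21, 21), 0.005,
            center=(0.0, 0.0))
        result = localize_from_thermogram(grid, tissue)
        assert "peak-on-boundary" in result.method_flags["warnings"]

    def test_noisy_grid_error_distribution(self, tissue,
                                           point_fixture_source):
        """Under 10% elevation noise the analytic inversion stays within
        the error magnitudes reported for the noisy regime: depth errors
        of at most tens of percent, intensity around ten percent."""
        errs = []
        for seed in range(60):
            grid = generate_synthetic_thermogram(
                point_fixture_source, tissue, (41, 41), 0.005,
                noise=NoiseSpec("elevation_percent", 0.10, seed=seed))
            r = localize_from_thermogram(grid, tissue)
            errs.append((abs(r.d_eff - 0.014) / 0.014,
                         abs(r.Q - 0.1) / 0.1))
        d_errs, q_errs = np.array(errs).T
        assert 0 < np.median(d_errs) < 0.662
        assert 0 < np.median(q_errs) < 0.10


class TestEstimateSource:
    def test_matches_closed_forms(self, tissue):
        est = estimate_source(20.0, 33.4, 35.2, 0.01, tissue)
        assert est.d_eff == pytest.approx(0.01 * math.sqrt(13.4 / 1.8),
                                          rel=1e-12)
        assert est.Q == pytest.approx(FOUR_PI * 8.77 * 1e-4 * 13.4 * 15.2 / 1.8,
                                      rel=1e-12)

    def test_depth_range_averaging(self, tissue):
        est = estimate_source(20.0, 33.4, 35.2, 0.01, tissue,
                              depth_range=(0.006, 0.01), n_depths=5)
        expected = FOUR_PI * tissue.h0 * 13.4 * (est.depth_grid**2 + 1e-4)
        np.testing.assert_allclose(est.Q_over_depths, expected, rtol=1e-12)
        assert est.Q_mean == pytest.approx(expected.mean(), rel=1e-12)
        # intensity grows with assumed depth
        assert np.all(np.diff(est.Q_over_depths) > 0)

    def test_invalid_depth_range_rejected(self, tissue):
        with pytest.raises(ValueError):
            estimate_source(20.0, 33.4, 35.2, 0.01, tissue,
                            depth_range=(0.0, 0.01))
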