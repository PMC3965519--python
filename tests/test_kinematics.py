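"""Pendulum solution, period measurement, and the 21-profile family."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_bvp
from scipy.special import ellipk

import plmotion as plm
from plmotion.kinematics import InsufficientDataError, _half_sweep_grid


def elliptic_period(L, g, theta0):
    """Closed-form large-amplitude period: the independent oracle."""
    k = math.sin(theta0 / 2.0)
    return 4.0 * math.sqrt(L / g) * float(ellipk(k * k))


class TestPendulumParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"L": -1.0},
            {"L": 0.0},
            {"g": 0.0},
            {"theta0": 0.0},
            {"theta0": math.pi / 2},
            {"theta0": -0.3},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            plm.PendulumParams(**kwargs)

    def test_amplitude_is_twice_release_angle(self, params):
        assert params.A == 2.0 * params.theta0

    def test_reference_period_near_printed_value(self, params):
        assert abs(params.T - 1.68) < 0.005
        assert params.design_period == 1.68


class TestSolvePendulum:
    def test_initial_conditions_exact(self, params, trace):
        assert trace.theta[0] == params.theta0
        assert trace.omega[0] == 0.0

    def test_energy_conserved_along_trace(self, params, trace):
        n = int(round(params.T * trace.sample_rate))
        e = trace.energy(params)[: n + 1]
        scale = 0.5 * params.L * np.max(trace.omega) ** 2 + params.g
        assert np.max(np.abs(e - e[0])) / scale < 1e-6

    def test_peak_speed_matches_energy_closed_form(self, params, trace):
        expected = math.sqrt(2.0 * (params.g / params.L) * (1 - math.cos(params.theta0)))
        assert np.max(np.abs(trace.omega)) == pytest.approx(expected, rel=1e-6)

    def test_low_sample_rate_rejected(self, params):
        with pytest.raises(ValueError, match="sample_rate"):
            plm.solve_pendulum(params, sample_rate=500)

    def test_bad_gravity_sign_rejected(self, params):
        with pytest.raises(ValueError, match="gravity_sign"):
            plm.solve_pendulum(params, gravity_sign=2)


class TestMeasurePeriod:
    @pytest.mark.parametrize("theta0", [math.pi / 12, math.pi / 6, math.pi / 4])
    def test_agrees_with_elliptic_integral(self, theta0):
        p = plm.PendulumParams(theta0=theta0)
        T = plm.measure_period(plm.solve_pendulum(p))
        assert T == pytest.approx(elliptic_period(p.L, p.g, theta0), rel=1e-4)

    def test_small_angle_limit(self):
        p = plm.PendulumParams(theta0=0.01)
        T = plm.measure_period(plm.solve_pendulum(p))
        assert T == pytest.approx(p.small_angle_period, rel=1e-3)

    def test_too_short_trace_rejected(self, params, trace):
        short = plm.MotionTrace(
            t=trace.t[:100], theta=trace.theta[:100], omega=trace.omega[:100],
            sample_rate=trace.sample_rate,
        )
        with pytest.raises(InsufficientDataError):
            plm.measure_period(short)


class TestHarmonicDeviation:
    def test_harmonic_compared_to_itself_is_zero(self):
        T = 1.7
        t = np.arange(20001) / 10_000.0
        w = 2 * math.pi / T
        tr = plm.MotionTrace(
            t=t, theta=0.8 * np.cos(w * t), omega=-0.8 * w * np.sin(w * t),
            sample_rate=10_000.0,
        )
        pos, vel = plm.harmonic_deviation(tr, period=T)
        assert pos < 1e-10 and vel < 1e-10

    def test_reference_deviations_match_printed_percentages(self, trace):
        pos, vel = plm.harmonic_deviation(trace)
        assert pos == pytest.approx(0.7, abs=0.15)
        assert vel == pytest.approx(1.3, abs=0.15)


class TestBasicProfiles:
    def test_constant_profile_value_and_integral(self, params):
        k5 = plm.constant_profile(params)
        expected = params.A / params.half_sweep  # (pi/2)/0.84 = 1.8700
        assert np.allclose(k5.v, expected)
        assert expected == pytest.approx(1.8700, abs=2e-4)
        assert k5.integral == pytest.approx(math.pi / 2, rel=1e-12)

    def test_one_g_profile_endpoints_and_peak(self, params):
        k10 = plm.one_g_profile(params)
        assert k10.v[0] == 0.0 and k10.v[-1] == 0.0
        expected_peak = math.sqrt(
            2.0 * (params.g / params.L) * (1 - math.cos(params.theta0))
        )
        assert k10.peak == pytest.approx(expected_peak, rel=1e-3)

    def test_reverse_gravity_reflect_mirrors_one_g(self, params):
        k0 = plm.reverse_gravity_profile(params)  # default: reflect
        k5 = plm.constant_profile(params)
        k10 = plm.one_g_profile(params)
        assert np.allclose(k0.v + k10.v, 2.0 * k5.v)
        assert k0.v[0] > k0.peak  # decelerates toward the midpoint
        assert k0.integral == pytest.approx(params.A, rel=1e-4)

    def test_reverse_gravity_shooting_duration_and_shape(self, params):
        k0 = plm.reverse_gravity_profile(params, method="shooting")
        assert k0.duration == pytest.approx(params.half_sweep, abs=1e-9)
        assert k0.v[0] > k0.peak > 0
        assert k0.integral == pytest.approx(params.A, rel=1e-4)

    def test_reverse_gravity_shooting_against_bvp_oracle(self, params):
        """Endpoint speed of the reversed-gravity sweep vs an independent BVP solve."""
        k = params.g / params.L
        half = params.half_sweep

        def ode(t, y):
            return np.vstack([y[1], k * np.sin(y[0])])

        def bc(ya, yb):
            return np.array([ya[0] - params.theta0, yb[0] + params.theta0])

        t = np.linspace(0, half, 201)
        y0 = np.vstack([np.linspace(params.theta0, -params.theta0, 201),
                        np.full(201, -params.A / half)])
        sol = solve_bvp(ode, bc, t, y0, tol=1e-8, max_nodes=20000)
        assert sol.success
        v0_oracle = abs(sol.sol(0.0)[1])
        shoot = plm.reverse_gravity_profile(params, method="shooting")
        assert shoot.v[0] == pytest.approx(v0_oracle, rel=1e-4)

    def test_amplified_profiles_equal_peak_spacing(self, params):
        k5 = plm.constant_profile(params)
        k10 = plm.one_g_profile(params)
        k15, k20 = plm.amplified_profiles(params)
        gap = k10.peak - k5.peak
        assert k15.peak - k10.peak == pytest.approx(gap, rel=1e-6)
        assert k20.peak - k15.peak == pytest.approx(gap, rel=1e-6)
        for p in (k15, k20):
            assert p.v[0] == 0.0 and p.v[-1] == 0.0
            assert p.integral == pytest.approx(math.pi / 2, rel=1e-6)
            assert p.family == "sin-power"


class TestProfileFamily:
    def test_basic_indices_and_labels(self, family):
        labels = {0: "-1g", 5: "0g", 10: "1g", 15: "2g", 20: "3g"}
        for i, lab in labels.items():
            assert family[i].g_level == lab
            assert family[i].lam is None

    def test_interpolation_endpoints_reproduce_basics(self, params, family):
        # lambda -> 0 and 1 must reduce exactly to the neighbouring basics
        k5, k10 = family[5], family[10]
        w0 = 1.0 * k5.v + 0.0 * k10.v
        w1 = 0.0 * k5.v + 1.0 * k10.v
        assert np.array_equal(w0, k5.v)
        assert np.array_equal(w1, k10.v)

    def test_k6_peak_is_weighted_basic_peaks(self, family):
        expected = 0.8 * family[5].peak + 0.2 * family[10].peak
        assert family[6].peak == pytest.approx(expected, rel=1e-12)

    def test_peak_monotone_for_upper_half(self, family):
        peaks = [family[i].peak for i in range(5, 21)]
        assert all(b > a for a, b in zip(peaks, peaks[1:]))

    def test_amplitude_conserved_for_all_21(self, params, family):
        for p in family:
            assert p.integral == pytest.approx(params.A, rel=1e-4)

    def test_symmetry_about_quarter_period(self, family):
        for p in family:
            assert p.symmetry_error() < 1e-3

    def test_json_round_trip(self, family, tmp_path):
        path = tmp_path / "profiles.json"
        family.to_json(path)
        back = plm.ProfileFamily.from_json(path)
        for a, b in zip(family, back):
            assert a.index == b.index and a.g_level == b.g_level
            assert np.allclose(a.v, b.v)


class TestIntegrateProfile:
    def test_high_rate_grid_has_16800_samples_per_period(self, family):
        tr = plm.integrate_profile(family[10], sample_rate_out=100)
        # 100 Hz output of the 10 kHz grid: 168 frames ~ 16800 high-rate samples
        assert len(tr) == 168
        n_high = int(round(plm.REFERENCE_PARAMS.design_period * plm.GENERATION_RATE_HZ))
        assert n_high == 16800

    def test_constant_profile_gives_triangle_wave(self, family):
        tr = plm.integrate_profile(family[5], sample_rate_out=1000)
        half = len(tr) // 2
        # theta decreases linearly then increases linearly
        d1 = np.diff(tr.theta[: half - 1])
        d2 = np.diff(tr.theta[half + 1 :])
        assert np.allclose(d1, d1[0]) and d1[0] < 0
        assert np.allclose(d2, d2[0]) and d2[0] > 0

    def test_one_g_positions_match_ode_solution(self, params, family, trace):
        tr = plm.integrate_profile(family[10], sample_rate_out=100)
        # compare against the RK4 angle on the (slightly faster) true time base
        scale = (plm.measure_period(trace) / 2.0) / params.half_sweep
        theta_ode = np.interp(tr.t * scale, trace.t, trace.theta)
        assert np.max(np.abs(tr.theta - theta_ode)) < 1e-3

    def test_sweep_reaches_opposite_endpoint(self, params, family):
        tr = plm.integrate_profile(family[10], direction_pattern="unidirectional",
                                   sample_rate_out=10_000)
        assert tr.theta[0] == pytest.approx(params.theta0, abs=1e-6)
        assert tr.theta[-1] == pytest.approx(-params.theta0, abs=1e-3)

    def test_non_integer_decimation_rejected(self, family):
        with pytest.raises(ValueError, match="integer"):
            plm.integrate_profile(family[10], sample_rate_high=10_000, sample_rate_out=300)


class TestAccelerationRatio:
    def test_constant_profile_has_zero_ratio(self, family):
        assert plm.acceleration_ratio(family[5]) == 0.0

    def test_k6_ratio_matches_arithmetic_oracle(self, params, family):
        # K6 = 0.8*K5 + 0.2*K10: endpoint 0.8*V0g, midpoint 0.8*V0g + 0.2*peak1g
        v0g = params.A / params.half_sweep
        peak1g = family[10].peak
        expected = (0.2 * peak1g) / v0g * 100.0
        assert plm.acceleration_ratio(family[6]) == pytest.approx(expected, rel=1e-3)
        assert plm.acceleration_ratio(family[6]) == pytest.approx(32.0, abs=1.0)

    def test_all_nonconstant_profiles_above_detection_threshold(self, family):
        ratios = plm.detectability_ratios(family)
        assert all(r > 25.0 for i, r in ratios.items() if i != 5)


class TestTraceIO:
    def test_round_trip(self, trace, tmp_path):
        path = tmp_path / "trace.csv"
        sub = plm.MotionTrace(
            t=trace.t[:500], theta=trace.theta[:500], omega=trace.omega[:500],
            sample_rate=trace.sample_rate,
        )
        plm.kinematics.write_trace_csv(sub, path)
        back = plm.kinematics.read_trace_csv(path)
        assert np.allclose(back.theta, sub.theta)
        assert np.allclose(back.omega, sub.omega)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(ValueError, match="header"):
            plm.kinematics.read_trace_csv(path)


@settings(max_examples=8, deadline=None, derandomize=True)
@given(
    L=st.floats(0.3, 2.0),
    theta0=st.floats(math.pi / 12, math.pi / 3),
)
def test_family_invariants_hold_across_parameters(L, theta0):
    """Amplitude conservation and ordered peaks for arbitrary valid pendulums."""
    p = plm.PendulumParams(L=L, theta0=theta0)
    fam = plm.build_family(p)
    for prof in fam:
        assert prof.integral == pytest.approx(p.A, rel=1e-4)
    peaks = [fam[i].peak for i in range(5, 21)]
    assert all(b > a for a, b in zip(peaks, peaks[1:]))


def test_half_sweep_grid_spacing(params):
    t = _half_sweep_grid(params)
    assert t[0] == 0.0 and t[-1] == pytest.approx(params.half_sweep)
    assert np.allclose(np.diff(t), 1.0 / plm.GENERATION_RATE_HZ)
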