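"""Kinematic estimators: differentiation, rigid-body omega, filtering,
peaks, phases, curve fits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from impactkin import (
    DegenerateGeometryError,
    KinematicSeries,
    KinematicsConfig,
    MarkerTrack,
    PhaseSegmentation,
    SimulationConfig,
    TrackedPair,
    analyze_pair,
    angular_acceleration,
    butterworth_lowpass,
    estimate_omega,
    estimate_omega_series,
    estimate_omega_windowed,
    fit_phase_curves,
    gradient_central,
    linear_head_kinematics,
    project_markers,
    round_sig,
    segment_phases,
    simulate_pose,
)
from impactkin.rigid_kinematics import peak_magnitude
from impactkin.synthetic_data import constant_rotation_pose

FR = 1000.0


def pair_from_positions(p1, p2, fr=FR):
    n = len(p1)
    t = np.arange(n) / fr
    return TrackedPair(
        MarkerTrack(1, t, p1[:, 0], p1[:, 1]),
        MarkerTrack(2, t, p2[:, 0], p2[:, 1]),
        frame_rate=fr,
    )


class TestGradientCentral:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ([5, 5, 5, 5], [0, 0, 0, 0]),
            ([0, 2, 4, 6], [2, 2, 2, 2]),
            ([0, 1, 4, 9, 16], [1, 2, 4, 6, 7]),  # x = t^2
        ],
    )
    def test_known_derivatives(self, series, expected):
        assert np.allclose(gradient_central(np.asarray(series, float), 1.0), expected)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            gradient_central(np.array([1.0, 2.0]), 1.0)


class TestLinearHeadKinematics:
    def test_shared_motion_equals_marker_motion(self):
        t = np.arange(20) / FR
        p = np.column_stack([np.sin(3 * t), t**2])
        pair = pair_from_positions(p, p + [0.0, 0.01])
        _, speed, _, accel_g = linear_head_kinematics(pair)
        v = gradient_central(p, 1 / FR)
        assert np.allclose(speed, np.linalg.norm(v, axis=1))

    def test_midpoint_of_marker_velocities(self):
        t = np.arange(10) / FR
        p1 = np.column_stack([1.0 * t, np.full_like(t, 0.01)])
        p2 = np.column_stack([3.0 * t, np.zeros_like(t)])
        _, speed, _, _ = linear_head_kinematics(pair_from_positions(p1, p2))
        assert np.allclose(speed, 2.0)

    def test_pure_rotation_about_midpoint_gives_zero_centre_speed(self):
        cfg = SimulationConfig()
        pose = constant_rotation_pose(5.0, 0.05, cfg)
        pair = project_markers(pose, cfg)
        _, speed, _, _ = linear_head_kinematics(pair)
        # symmetric markers cancel exactly
        assert speed.max() <= 1e-12

    def test_g_conversion_exact(self, noiseless_analysis):
        _, series, _ = noiseless_analysis
        assert np.allclose(
            series.head_accel_g * 9.80665, series.head_accel, rtol=0, atol=1e-9
        )


class TestEstimateOmega:
    def test_pure_translation_gives_zero(self):
        assert estimate_omega((1.0, 2.0), (1.0, 2.0), (0.0, 0.05)) == 0.0

    def test_closed_form_examples(self):
        # delta along y, relative velocity along -x => ccw 2 rad/s
        assert estimate_omega((-0.02, 0.0), (0.0, 0.0), (0.0, 0.01)) == pytest.approx(2.0)
        # delta along x, relative velocity along +y => ccw 3 rad/s
        assert estimate_omega((0.0, 0.03), (0.0, 0.0), (0.01, 0.0)) == pytest.approx(3.0)

    def test_coincident_markers_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            estimate_omega((1.0, 0.0), (0.0, 0.0), (0.0, 0.0))

    @given(
        ox=st.floats(-0.5, 0.5),
        oy=st.floats(-0.5, 0.5),
    )
    def test_translation_invariance(self, ox, oy):
        """Shifting both marker tracks by a constant leaves omega
        bit-identical: the estimator sees only relative geometry."""
        cfg = SimulationConfig(duration=5e-3)
        pair = project_markers(simulate_pose(cfg), cfg)
        shifted = TrackedPair(
            MarkerTrack(1, pair.times, pair.track1.x + ox, pair.track1.y + oy),
            MarkerTrack(2, pair.times, pair.track2.x + ox, pair.track2.y + oy),
            frame_rate=cfg.frame_rate,
        )
        a = estimate_omega_series(pair)
        b = estimate_omega_series(shifted)
        assert np.max(np.abs(a - b)) <= 1e-12 * max(1.0, np.max(np.abs(a)))


class TestEstimateOmegaWindowed:
    def test_static_rotation_window_matches_single_frame(self):
        """Three identical frames of geometry: the stacked estimate
        equals the single-frame closed form."""
        cfg = SimulationConfig()
        pose = constant_rotation_pose(4.0, 0.01, cfg)
        pair = project_markers(pose, cfg)
        v1, v2, _, _ = (
            gradient_central(pair.track1.positions, pair.track1.dt),
            gradient_central(pair.track2.positions, pair.track2.dt),
            None,
            None,
        )
        i = 5
        single = estimate_omega(v1[i], v2[i], pair.delta[i])
        windowed = estimate_omega_windowed(pair, i)
        assert windowed == pytest.approx(single, abs=1e-12)

    def test_constant_rotation_recovered(self):
        cfg = SimulationConfig()
        pair = project_markers(constant_rotation_pose(5.0, 0.05, cfg), cfg)
        omega = estimate_omega_series(pair)
        assert omega[5] == pytest.approx(5.0, rel=1e-3)

    def test_even_window_rejected(self):
        cfg = SimulationConfig(duration=5e-3)
        pair = project_markers(simulate_pose(cfg), cfg)
        with pytest.raises(ValueError, match="odd"):
            estimate_omega_series(pair, window_frames=2)


class TestButterworth:
    def test_dc_gain_unity(self):
        x = np.full(5000, 3.7)
        y = butterworth_lowpass(x, fs=3230.0)
        assert np.max(np.abs(y - 3.7)) <= 1e-9

    def test_cutoff_amplitude_ratio_half(self):
        """Two zero-phase passes of an order-4 Butterworth give
        |H|^2 = 1/2 at the cutoff frequency."""
        fs, f0 = 3230.0, 10.0
        t = np.arange(int(6 * fs)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        y = butterworth_lowpass(x, fs=fs, cutoff=f0, order=4)
        mid = slice(len(t) // 3, 2 * len(t) // 3)
        # least-squares sine amplitude over the steady-state interior
        basis = np.column_stack(
            [np.sin(2 * np.pi * f0 * t[mid]), np.cos(2 * np.pi * f0 * t[mid])]
        )
        coef, *_ = np.linalg.lstsq(basis, y[mid], rcond=None)
        assert np.hypot(*coef) == pytest.approx(0.5, rel=0.02)

    def test_zero_phase_preserves_symmetric_pulse_peak_time(self):
        fs = 3230.0
        t = np.arange(int(2 * fs)) / fs
        x = np.exp(-0.5 * ((t - 1.0) / 0.02) ** 2)
        y = butterworth_lowpass(x, fs=fs)
        assert np.argmax(y) == np.argmax(x)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            butterworth_lowpass(np.zeros(100), fs=100.0, cutoff=60.0)


class TestAngularAcceleration:
    def test_constant_omega_zero_alpha(self):
        assert np.allclose(angular_acceleration(np.full(10, 7.0), 1e-3), 0.0)

    def test_linear_ramp(self):
        n = 324
        omega = np.linspace(0.0, 100.0, n)
        dt = 0.1 / (n - 1)
        alpha = angular_acceleration(omega, dt)
        assert np.allclose(alpha, 1000.0)

    def test_matches_analytic_alpha_quadratically(self):
        """Central-differenced analytic omega converges to the analytic
        angular acceleration at O(dt^2)."""
        errs = {}
        for fs in (20000.0, 40000.0):
            pose = simulate_pose(SimulationConfig(frame_rate=fs, duration=0.02))
            alpha = angular_acceleration(pose.omega, 1.0 / fs)
            errs[fs] = np.max(np.abs(alpha - pose.alpha)[2:-2])
        assert errs[40000.0] < errs[20000.0] / 3.0


class TestRoundSig:
    @pytest.mark.parametrize(
        "x,n,expected",
        [
            (87_300, 1, 90_000),
            (0.0, 1, 0.0),
            (-472.6, 2, -470.0),
            (95_000, 1, 100_000),  # half away from zero
            (-0.0351, 2, -0.035),
            (2.5e-4, 1, 3e-4),
        ],
    )
    def test_examples(self, x, n, expected):
        assert round_sig(x, n) == pytest.approx(expected, rel=1e-12)

    def test_invalid_digits(self):
        with pytest.raises(ValueError):
            round_sig(1.0, 0)


class TestPeaks:
    def test_monotone_series_peaks_at_final_sample(self):
        t = np.arange(5.0)
        mag, when = peak_magnitude(np.array([0.0, 1, 2, 3, 4]), t)
        assert (mag, when) == (4.0, 4.0)

    def test_magnitude_convention(self):
        mag, when = peak_magnitude(np.array([0.0, 3, -5, 2]), np.arange(4.0))
        assert (mag, when) == (5.0, 2.0)

    def test_tie_broken_by_earliest_time(self):
        mag, when = peak_magnitude(np.array([1.0, 5, 2, -5, 0]), np.arange(5.0))
        assert (mag, when) == (5.0, 1.0)

    def test_default_simulation_recovers_configured_peak_omega(
        self, default_config, noiseless_analysis
    ):
        _, _, summary = noiseless_analysis
        assert summary.peak_angular_velocity == pytest.approx(
            default_config.peak_angular_velocity_primary, rel=0.01
        )

    def test_reported_alpha_is_one_significant_digit(self, noiseless_analysis):
        _, _, summary = noiseless_analysis
        reported = summary.reported_angular_acceleration
        assert reported == round_sig(summary.peak_angular_acceleration, 1)


class TestSegmentPhases:
    def test_zero_rotation_degenerate(self):
        t = np.arange(100) / FR
        z = np.zeros_like(t)
        series = KinematicSeries(t, *(np.zeros((100, 2)),) * 3, z, z, z, z, z, z, z)
        seg = segment_phases(series)
        assert seg.degenerate and seg.t_linear_end == 0.0

    def test_default_simulation_linear_phase_end(
        self, default_config, noiseless_analysis
    ):
        """The recovered end of the linear phase falls within 2 frames
        of the configured vertical-translation duration."""
        _, series, _ = noiseless_analysis
        seg = segment_phases(series)
        dt = 1.0 / default_config.frame_rate
        assert abs(seg.t_linear_end - default_config.phase1_duration) <= 2 * dt

    def test_zero_threshold_limit(self, noiseless_analysis):
        _, series, _ = noiseless_analysis
        seg = segment_phases(series, threshold_frac=0.0)
        first_nonzero = series.times[np.flatnonzero(np.abs(series.omega_raw) > 0)[0]]
        assert seg.t_linear_end == first_nonzero


class TestFitPhaseCurves:
    def _series_with(self, t, speed=None, omega=None):
        n = len(t)
        z = np.zeros(n)
        z2 = np.zeros((n, 2))
        return KinematicSeries(
            t,
            z2,
            z2,
            z2,
            speed if speed is not None else z,
            z,
            z,
            omega if omega is not None else z,
            z,
            z,
            z,
        )

    def test_exact_cubic_recovered(self):
        t = np.arange(200) / FR
        omega = 2.0 - 3.0 * t + 4.0 * t**2 + 5.0 * t**3
        series = self._series_with(t, omega=omega)
        phases = PhaseSegmentation(t_linear_end=0.0, t_primary_end=t[99])
        fits = fit_phase_curves(series, phases)
        seg = fits["omega_secondary"]
        tt0 = t[100]
        expected = np.polyfit(t[100:] - tt0, omega[100:], 3)
        assert np.allclose(seg["coeffs"], expected, atol=1e-8)
        assert seg["rmse"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_data_zero_rmse(self):
        t = np.arange(100) / FR
        series = self._series_with(t, speed=np.full(100, 2.5))
        phases = PhaseSegmentation(t_linear_end=t[20], t_primary_end=t[60])
        fits = fit_phase_curves(series, phases)
        assert fits["speed_rise"]["rmse"] == pytest.approx(0.0, abs=1e-10)
        assert fits["speed_decay"]["rmse"] == pytest.approx(0.0, abs=1e-10)

    def test_noisy_fit_rmse_sits_at_noise_level(self, rng):
        """The least-squares fit absorbs the underlying pulse, leaving
        residual RMSE at (on average just below) the noise sd."""
        t = np.arange(40) / FR
        sd = 0.3
        rmses = []
        for _ in range(20):
            truth = 2 - 3 * t + 400 * t**2 - 900 * t**3
            noisy = truth + rng.normal(0, sd, len(t))
            series = self._series_with(t, omega=noisy)
            phases = PhaseSegmentation(t_linear_end=0.0, t_primary_end=t[-1] + 1)
            fits = fit_phase_curves(series, phases)
            rmses.append(fits["omega_primary"]["rmse"])
        assert np.mean(rmses) < sd

    def test_underdetermined_segment_rejected(self):
        t = np.arange(10) / FR
        series = self._series_with(t, omega=np.arange(10.0))
        phases = PhaseSegmentation(t_linear_end=0.0, t_primary_end=t[-3])
        with pytest.raises(ValueError, match="too few"):
            fit_phase_curves(series, phases)


def test_analyze_pair_series_share_time_base(noiseless_analysis):
    _, series, _ = noiseless_analysis
    n = len(series.times)
    for name in (
        "head_speed",
        "head_accel_g",
        "omega_raw",
        "omega_filtered",
        "alpha",
        "alpha_unfiltered",
    ):
        assert len(getattr(series, name)) == n
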