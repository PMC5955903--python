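"""Rigid-body kinematics from a tracked marker pair.

The head is treated as a rigid body moving in the sagittal plane and
observed through two tracked markers.  Per-marker linear velocity and
acceleration come from central differences of the (repeat-averaged)
positions; head-centre linear kinematics are the average over the two
markers.  The planar angular velocity follows from the rigid-body
relations between the two marker velocities,

    V1x = V2x - omega * Dy
    V1y = V2y + omega * Dx

where (Dx, Dy) = p1 - p2 is the relative position of marker 1 with
respect to marker 2.  The least-squares omega for these two residuals
is available in closed form, and stacking the residuals over three
successive frames (the default) suppresses annotation noise.  For
angular acceleration the angular-velocity series is low-pass filtered
(zero-phase Butterworth, 10 Hz default) before a three-point central
difference; an unfiltered angular-acceleration series is retained
alongside because a 10 Hz cutoff strongly attenuates millisecond-scale
transients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .tracking_io import TrackedPair

__all__ = [
    "STANDARD_GRAVITY",
    "KinematicsConfig",
    "KinematicSeries",
    "KinematicSummary",
    "PhaseSegmentation",
    "DegenerateGeometryError",
    "gradient_central",
    "linear_head_kinematics",
    "estimate_omega",
    "estimate_omega_series",
    "estimate_omega_windowed",
    "butterworth_lowpass",
    "angular_acceleration",
    "round_sig",
    "peak_magnitude",
    "extract_peaks",
    "segment_phases",
    "fit_phase_curves",
    "analyze_pair",
]

#: standard gravity, m/s^2, used to report linear acceleration in g
STANDARD_GRAVITY = 9.80665


class DegenerateGeometryError(ValueError):
    """Raised when the marker geometry cannot constrain omega."""


@dataclass(frozen=True)
class KinematicsConfig:
    """Tunable parameters of the kinematic pipeline.

    ``filter_cutoff_hz``/``filter_order`` control the Butterworth
    low-pass applied to angular velocity on the angular-acceleration
    path only; set ``filter_omega_for_peaks`` to also report peak
    angular velocity from the filtered series.  ``window_frames`` is
    the number of successive frames stacked in the angular-velocity
    least squares.  Peak search excludes ``peak_edge_exclusion``
    samples at each end to avoid one-sided-difference edge artifacts.
    """

    filter_cutoff_hz: float = 10.0
    filter_order: int = 4
    zero_phase: bool = True
    filter_omega_for_peaks: bool = False
    window_frames: int = 3
    average_vectors: bool = True  # vector (not magnitude) averaging of markers
    peak_edge_exclusion: int = 1
    phase_threshold_frac: float = 0.2


@dataclass
class KinematicSeries:
    """Per-frame kinematics of one recording; all series share ``times``."""

    times: np.ndarray  # s
    v1: np.ndarray  # (N, 2) m/s
    v2: np.ndarray  # (N, 2) m/s
    head_velocity: np.ndarray  # (N, 2) m/s
    head_speed: np.ndarray  # m/s
    head_accel: np.ndarray  # m/s^2 (magnitude)
    head_accel_g: np.ndarray  # in units of standard gravity
    omega_raw: np.ndarray  # rad/s
    omega_filtered: np.ndarray  # rad/s
    alpha: np.ndarray  # rad/s^2, from filtered omega
    alpha_unfiltered: np.ndarray  # rad/s^2, from raw omega


@dataclass
class KinematicSummary:
    """Peak magnitudes and peak times (ms after recording start).

    ``peak_angular_acceleration`` is the raw extracted value;
    ``reported_angular_acceleration`` rounds it to one significant
    digit, the reporting convention that acknowledges digital
    filtering.  ``scaled`` marks human-equivalent values produced by
    interspecies scaling; ``scaling_rule`` records the rule applied.
    """

    peak_linear_accel_g: float
    t_peak_linear_accel_ms: float
    peak_linear_velocity: float
    t_peak_linear_velocity_ms: float
    peak_angular_velocity: float
    t_peak_angular_velocity_ms: float
    peak_angular_acceleration: float
    t_peak_angular_acceleration_ms: float
    scaled: bool = False
    scaling_rule: str | None = None
    animal_id: str = "unknown"
    energy_label_J: float | None = None

    @property
    def reported_angular_acceleration(self) -> float:
        return round_sig(self.peak_angular_acceleration, 1)

    def to_dict(self) -> dict:
        d = {
            "peak_linear_accel_g": self.peak_linear_accel_g,
            "t_peak_linear_accel_ms": self.t_peak_linear_accel_ms,
            "peak_linear_velocity_m_s": self.peak_linear_velocity,
            "t_peak_linear_velocity_ms": self.t_peak_linear_velocity_ms,
            "peak_angular_velocity_rad_s": self.peak_angular_velocity,
            "t_peak_angular_velocity_ms": self.t_peak_angular_velocity_ms,
            "peak_angular_acceleration_rad_s2": self.peak_angular_acceleration,
            "reported_angular_acceleration_rad_s2": self.reported_angular_acceleration,
            "t_peak_angular_acceleration_ms": self.t_peak_angular_acceleration_ms,
            "scaled": self.scaled,
            "scaling_rule": self.scaling_rule,
            "animal_id": self.animal_id,
            "energy_label_J": self.energy_label_J,
        }
        return d


@dataclass
class PhaseSegmentation:
    """Boundaries between linear, primary-rotation and secondary-rotation phases."""

    t_linear_end: float  # s
    t_primary_end: float  # s
    degenerate: bool = False
    method: str = "omega-threshold"


# ---------------------------------------------------------------------------
# Differentiation


def gradient_central(series: np.ndarray, dt: float) -> np.ndarray:
    """Central-difference derivative with one-sided endpoints.

    Interior: (x[i+1] - x[i-1]) / (2 dt); endpoints use first
    differences.  Output length equals input length.  Exact for
    linear series everywhere and second-order accurate in the
    interior.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise ValueError("need at least 3 samples for central differences")
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = np.empty_like(series)
    out[1:-1] = (series[2:] - series[:-2]) / (2.0 * dt)
    out[0] = (series[1] - series[0]) / dt
    out[-1] = (series[-1] - series[-2]) / dt
    return out


def _marker_derivatives(pair: TrackedPair) -> tuple[np.ndarray, ...]:
    dt = 1.0 / pair.frame_rate
    p1, p2 = pair.track1.positions, pair.track2.positions
    v1 = gradient_central(p1, dt)
    v2 = gradient_central(p2, dt)
    a1 = gradient_central(v1, dt)
    a2 = gradient_central(v2, dt)
    return v1, v2, a1, a2


def linear_head_kinematics(
    pair: TrackedPair, config: KinematicsConfig = KinematicsConfig()
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Head-centre linear velocity and acceleration from both markers.

    With symmetric markers the component-wise (vector) average of the
    marker velocities is exactly the centre velocity of the rigid
    body; ``config.average_vectors=False`` averages magnitudes instead
    (an alternative reading of "average of each tracking point").

    Returns ``(head_velocity (N,2), head_speed, head_accel_magnitude,
    head_accel_g)``.
    """
    v1, v2, a1, a2 = _marker_derivatives(pair)
    head_v = 0.5 * (v1 + v2)
    head_a = 0.5 * (a1 + a2)
    if config.average_vectors:
        speed = np.linalg.norm(head_v, axis=1)
        accel = np.linalg.norm(head_a, axis=1)
    else:
        speed = 0.5 * (
            np.linalg.norm(v1, axis=1) + np.linalg.norm(v2, axis=1)
        )
        accel = 0.5 * (
            np.linalg.norm(a1, axis=1) + np.linalg.norm(a2, axis=1)
        )
    return head_v, speed, accel, accel / STANDARD_GRAVITY


# ---------------------------------------------------------------------------
# Angular velocity (rigid-body least squares)


def estimate_omega(
    v1: np.ndarray, v2: np.ndarray, delta: np.ndarray
) -> float:
    """Closed-form least-squares angular velocity from one frame.

    Minimizes the squared residuals of the planar rigid-body velocity
    relations; the problem is quadratic in omega with unique minimizer

        omega = (Dx*(V1y - V2y) - Dy*(V1x - V2x)) / (Dx^2 + Dy^2),

    counter-clockwise positive.
    """
    dx, dy = float(delta[0]), float(delta[1])
    denom = dx * dx + dy * dy
    if denom == 0.0:
        raise DegenerateGeometryError("coincident markers: |delta| = 0")
    dvx = float(v1[0]) - float(v2[0])
    dvy = float(v1[1]) - float(v2[1])
    return (dx * dvy - dy * dvx) / denom


def estimate_omega_series(
    pair: TrackedPair, window_frames: int = 3
) -> np.ndarray:
    """Windowed least-squares angular velocity for every frame.

    For each frame the rigid-body residuals are stacked over
    ``window_frames`` successive frames (the frame and its
    neighbours), each with its own per-frame relative position, and a
    single omega minimizes the stacked squared error:

        omega = sum_t (Dx_t*dVy_t - Dy_t*dVx_t) / sum_t (Dx_t^2 + Dy_t^2)

    Boundary frames use the nearest full window.  ``window_frames=1``
    reduces to the single-frame estimator.
    """
    if window_frames < 1 or window_frames % 2 == 0:
        raise ValueError("window_frames must be a positive odd integer")
    v1, v2, _, _ = _marker_derivatives(pair)
    delta = pair.delta
    dv = v1 - v2
    num = delta[:, 0] * dv[:, 1] - delta[:, 1] * dv[:, 0]
    den = np.einsum("ij,ij->i", delta, delta)
    n = len(num)
    if n < window_frames:
        raise ValueError("recording shorter than the estimation window")
    half = window_frames // 2
    # nearest full window: clamp the window centre into the interior
    centers = np.clip(np.arange(n), half, n - 1 - half)
    kernel = np.ones(window_frames)
    num_sum = np.convolve(num, kernel, mode="valid")  # len n - 2*half
    den_sum = np.convolve(den, kernel, mode="valid")
    if np.any(den_sum == 0.0):
        raise DegenerateGeometryError("degenerate window: markers coincide")
    return num_sum[centers - half] / den_sum[centers - half]


def estimate_omega_windowed(
    pair: TrackedPair, frame_index: int, window_frames: int = 3
) -> float:
    """Windowed omega at a single frame (see estimate_omega_series)."""
    series = estimate_omega_series(pair, window_frames)
    return float(series[frame_index])


# ---------------------------------------------------------------------------
# Filtering and angular acceleration


def butterworth_lowpass(
    series: np.ndarray,
    fs: float,
    cutoff: float = 10.0,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Low-pass Butterworth filter of an evenly sampled series.

    Zero-phase (forward-backward) by default, which preserves the
    timing of peaks; the squared magnitude response of the two passes
    gives a gain of 1/2 at the cutoff frequency.  Output length equals
    input length.
    """
    series = np.asarray(series, dtype=float)
    if cutoff >= fs / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {fs / 2:g} Hz")
    if len(series) <= 3 * order:
        raise ValueError("series too short for the filter order")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, series)
    return signal.sosfilt(sos, series)


def angular_acceleration(omega: np.ndarray, dt: float) -> np.ndarray:
    """Three-point central difference of angular velocity."""
    return gradient_central(np.asarray(omega, dtype=float), dt)


# ---------------------------------------------------------------------------
# Reporting helpers


def round_sig(x: float, n_digits: int = 1) -> float:
    """Round to ``n_digits`` significant digits, half away from zero.

    Used to report angular acceleration to one significant digit in
    acknowledgement of digital filtering; 0 maps to 0.
    """
    if n_digits < 1:
        raise ValueError("n_digits must be >= 1")
    if x == 0 or not math.isfinite(x):
        return float(x)
    exponent = math.floor(math.log10(abs(x)))
    quantum = 10.0 ** (exponent - n_digits + 1)
    return math.copysign(math.floor(abs(x) / quantum + 0.5) * quantum, x)


def peak_magnitude(
    series: np.ndarray, times: np.ndarray, exclude: int = 0
) -> tuple[float, float]:
    """Largest |value| and its time; earliest time wins ties.

    ``exclude`` drops that many samples at each end of the search
    (edge artifacts of one-sided differences).
    """
    mag = np.abs(np.asarray(series, dtype=float))
    if exclude > 0 and len(mag) > 2 * exclude:
        sl = slice(exclude, len(mag) - exclude)
    else:
        sl = slice(None)
    idx = int(np.argmax(mag[sl])) + (sl.start or 0)
    return float(mag[idx]), float(times[idx])


def extract_peaks(
    series: KinematicSeries,
    config: KinematicsConfig = KinematicsConfig(),
    *,
    animal_id: str = "unknown",
    energy_label_J: float | None = None,
) -> KinematicSummary:
    """Peak magnitudes and times (ms) of the four kinematic quantities.

    Angular-velocity peaks come from the raw (unfiltered) series
    unless ``config.filter_omega_for_peaks`` is set; the angular
    acceleration peak uses the filtered-omega path, the convention
    under which it is reported to one significant digit.
    """
    t = series.times
    ex = config.peak_edge_exclusion
    omega = (
        series.omega_filtered if config.filter_omega_for_peaks else series.omega_raw
    )
    pa, ta = peak_magnitude(series.head_accel_g, t, ex)
    pv, tv = peak_magnitude(series.head_speed, t, ex)
    pw, tw = peak_magnitude(omega, t, ex)
    pal, tal = peak_magnitude(series.alpha, t, ex)
    return KinematicSummary(
        peak_linear_accel_g=pa,
        t_peak_linear_accel_ms=ta * 1e3,
        peak_linear_velocity=pv,
        t_peak_linear_velocity_ms=tv * 1e3,
        peak_angular_velocity=pw,
        t_peak_angular_velocity_ms=tw * 1e3,
        peak_angular_acceleration=pal,
        t_peak_angular_acceleration_ms=tal * 1e3,
        animal_id=animal_id,
        energy_label_J=energy_label_J,
    )


# ---------------------------------------------------------------------------
# Phase segmentation and descriptive curve fits


def segment_phases(
    series: KinematicSeries,
    threshold_frac: float = 0.2,
) -> PhaseSegmentation:
    """Segment the recording into linear, primary- and secondary-rotation phases.

    The linear phase ends when |omega| first exceeds ``threshold_frac``
    of its peak; the primary rotation ends at the first subsequent
    local minimum of |omega| below that threshold (the hand-off to the
    slow secondary rotation).  A recording with no angular excursion
    is flagged degenerate with both boundaries at 0.
    """
    omega = np.abs(series.omega_raw)
    t = series.times
    peak = float(omega.max())
    if peak == 0.0:
        return PhaseSegmentation(0.0, 0.0, degenerate=True)
    thr = threshold_frac * peak
    above = np.flatnonzero(omega > thr) if threshold_frac > 0 else np.flatnonzero(omega > 0)
    if above.size == 0:
        return PhaseSegmentation(0.0, 0.0, degenerate=True)
    i_lin = int(above[0])
    i_peak = int(np.argmax(omega))
    i_primary = len(t) - 1
    for i in range(max(i_peak, i_lin) + 1, len(t) - 1):
        if omega[i] <= thr and omega[i] <= omega[i - 1] and omega[i] <= omega[i + 1]:
            i_primary = i
            break
    return PhaseSegmentation(float(t[i_lin]), float(t[i_primary]))


def fit_phase_curves(
    series: KinematicSeries,
    phases: PhaseSegmentation,
    model: str = "poly3",
) -> dict[str, dict[str, object]]:
    """Descriptive least-squares curve fits per phase segment.

    Fits each kinematic quantity over each phase segment with a cubic
    polynomial by default (``model="polyK"`` for degree K).  Linear
    velocity and linear acceleration are additionally split at their
    peak into rise and decay segments, which are fit separately.  The
    fits are for reporting and visualization only and never feed peak
    extraction.

    Returns a mapping ``{segment_name: {"coeffs": ndarray, "rmse":
    float, "t": (start, end)}}``.
    """
    if not model.startswith("poly"):
        raise ValueError(f"unknown model {model!r}")
    degree = int(model[4:])
    t = series.times
    segments: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def add_segment(name: str, mask: np.ndarray, values: np.ndarray) -> None:
        segments[name] = (t[mask], values[mask])

    lin_mask = t <= phases.t_linear_end
    prim_mask = (t > phases.t_linear_end) & (t <= phases.t_primary_end)
    sec_mask = t > phases.t_primary_end
    add_segment("omega_primary", prim_mask, series.omega_raw)
    add_segment("omega_secondary", sec_mask, series.omega_raw)
    if lin_mask.any():
        add_segment("speed_linear_phase", lin_mask, series.head_speed)
    for name, values in (
        ("speed", series.head_speed),
        ("accel", series.head_accel),
    ):
        i_pk = int(np.argmax(values))
        add_segment(f"{name}_rise", np.arange(len(t)) <= i_pk, values)
        add_segment(f"{name}_decay", np.arange(len(t)) >= i_pk, values)

    out: dict[str, dict[str, object]] = {}
    for name, (tt, vv) in segments.items():
        if len(tt) == 0:
            continue
        if len(tt) == 1 or np.ptp(vv) == 0:
            deg = 0  # constant data: constant-term-only fit
        elif len(tt) <= degree:
            raise ValueError(
                f"segment {name!r} has {len(tt)} samples, too few for degree {degree}"
            )
        else:
            deg = degree
        coeffs = np.polyfit(tt - tt[0], vv, deg)
        resid = vv - np.polyval(coeffs, tt - tt[0])
        out[name] = {
            "coeffs": coeffs,
            "rmse": float(np.sqrt(np.mean(resid**2))),
            "t": (float(tt[0]), float(tt[-1])),
        }
    return out


# ---------------------------------------------------------------------------
# Pipeline entry point


def analyze_pair(
    pair: TrackedPair, config: KinematicsConfig = KinematicsConfig()
) -> tuple[KinematicSeries, KinematicSummary]:
    """Full kinematic analysis of one recording.

    Differentiates the repeat-averaged tracks, estimates angular
    velocity with the windowed rigid-body least squares, filters it
    for the angular-acceleration path, and extracts peaks.
    """
    dt = 1.0 / pair.frame_rate
    v1, v2, _, _ = _marker_derivatives(pair)
    head_v, speed, accel, accel_g = linear_head_kinematics(pair, config)
    omega_raw = estimate_omega_series(pair, config.window_frames)
    omega_filt = butterworth_lowpass(
        omega_raw,
        fs=pair.frame_rate,
        cutoff=config.filter_cutoff_hz,
        order=config.filter_order,
        zero_phase=config.zero_phase,
    )
    alpha = angular_acceleration(omega_filt, dt)
    alpha_unf = angular_acceleration(omega_raw, dt)
    series = KinematicSeries(
        times=pair.times,
        v1=v1,
        v2=v2,
        head_velocity=head_v,
        head_speed=speed,
        head_accel=accel,
        head_accel_g=accel_g,
        omega_raw=omega_raw,
        omega_filtered=omega_filt,
        alpha=alpha,
        alpha_unfiltered=alpha_unf,
    )
    summary = extract_peaks(
        series,
        config,
        animal_id=pair.animal_id,
        energy_label_J=pair.energy_label_J,
    )
    return series, summary
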