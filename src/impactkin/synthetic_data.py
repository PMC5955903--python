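"""Ground-truth rigid-body head trajectories and noisy marker projection.

The generator emulates the three-phase sagittal-plane head motion seen
in closed-head impact devices with a protective cradle:

1. a brief (~1.5 ms) vertical translation of the head while the piston
   is in contact,
2. a fast (~2 ms) primary rotation about the shoulders, during which
   angular velocity rises to its peak and falls back to the slower
   secondary rate,
3. a slow (~200 ms) secondary rotation of animal and cradle through a
   fixed total angle (175 degrees by default) about an added pivot.

Motion is prescribed, not emergent: every phase is built from
raised-cosine acceleration pulses, which are C1-continuous and have
closed-form velocity and position integrals, so the generated series
carry exact analytic ground truth for parameter-recovery tests.

Markers are projected as ``centre + R(theta) @ offset`` and annotation
noise is added as iid Gaussian per coordinate per annotation repeat,
mimicking independent manual isolations of each marker.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .tracking_io import MarkerTrack, TrackedPair, average_annotations

__all__ = [
    "SimulationConfig",
    "PoseTrajectory",
    "RaisedCosinePulse",
    "ConfigError",
    "simulate_pose",
    "project_markers",
    "simulate_recording",
    "render_marker_mask",
]


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    """Specification of a three-phase ground-truth head motion.

    Defaults reproduce the regime of the modelled impacts: 3230
    frames/s video, ~1400 g peak linear acceleration, 200 rad/s peak
    primary angular velocity, and a 175-degree secondary rotation.

    Parameters
    ----------
    frame_rate : float, samples/s
    duration : float or None, s
        Recording length; defaults to the end of the secondary
        rotation.
    phase1_duration : float, s
        Vertical-translation (piston contact) phase.
    phase2_duration : float, s
        Nominal primary-rotation window about the shoulders; sets the
        head-centre deceleration time and the fast angular onset.
    phase3_duration : float, s
        Secondary rotation about the added pivot, measured from the
        start of its plateau.
    peak_linear_accel : float, m/s^2
        Amplitude of the phase-1 vertical acceleration pulse.
    peak_angular_velocity_primary : float, rad/s
    omega_peak_time : float, s
        Time at which angular velocity reaches its primary peak
        (default 5 ms, the observed peak timing); the angular rate
        climbs fast over the nominal primary window and approaches
        its maximum gradually after it.
    omega_onset_fraction : float
        Fraction of the primary peak reached by the fast onset pulse.
    omega_decay_duration : float, s
        Width of the decay from the primary peak down to the slow
        secondary-rotation rate.
    secondary_rotation_total : float, rad
        Total orientation change over the secondary-rotation phase.
    secondary_stop_duration : float, s
        Width of the final deceleration that brings the secondary
        rotation to rest at the catch.
    marker_offsets : two (x, y) body-frame vectors, m
        Marker positions relative to the head centre; the default
        10 mm separation is a configurable placeholder.
    noise_sigma : float, m
        Annotation noise sd per coordinate per repeat.
    n_annotation_repeats : int
    seed : int
    """

    frame_rate: float = 3230.0
    duration: float | None = None
    phase1_duration: float = 1.5e-3
    phase2_duration: float = 2e-3
    phase3_duration: float = 0.2
    peak_linear_accel: float = 1.371e4  # ~1400 g
    peak_angular_velocity_primary: float = 200.0
    omega_peak_time: float = 5e-3
    omega_onset_fraction: float = 0.8
    omega_decay_duration: float = 5e-3
    secondary_rotation_total: float = math.radians(175.0)  # 3.054 rad
    secondary_stop_duration: float = 0.05
    marker_offsets: tuple[tuple[float, float], tuple[float, float]] = (
        (5e-3, 0.0),
        (-5e-3, 0.0),
    )
    noise_sigma: float = 0.0
    n_annotation_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        for name in ("phase1_duration", "phase2_duration", "phase3_duration"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.duration is not None and self.duration <= 0:
            raise ConfigError("duration must be positive")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be non-negative")
        if self.peak_angular_velocity_primary < 0:
            raise ConfigError("peak_angular_velocity_primary must be >= 0")
        if self.secondary_rotation_total < 0:
            raise ConfigError("secondary_rotation_total must be >= 0")
        if not 0.0 < self.omega_onset_fraction <= 1.0:
            raise ConfigError("omega_onset_fraction must be in (0, 1]")
        if self.omega_peak_time <= self.phase1_duration + 0.5 * self.phase2_duration:
            raise ConfigError(
                "omega_peak_time must fall after the fast angular onset "
                "(phase1_duration + phase2_duration / 2)"
            )
        if self.omega_decay_duration <= 0:
            raise ConfigError("omega_decay_duration must be positive")
        if self.secondary_stop_duration <= 0:
            raise ConfigError("secondary_stop_duration must be positive")
        if self.n_annotation_repeats < 1:
            raise ConfigError("n_annotation_repeats must be >= 1")
        o1, o2 = (np.asarray(o, dtype=float) for o in self.marker_offsets)
        if np.allclose(o1, o2):
            raise ConfigError("marker offsets must be distinct")
        dt = 1.0 / self.frame_rate
        for name in ("phase1_duration", "phase2_duration", "phase3_duration"):
            if getattr(self, name) < 3 * dt:
                warnings.warn(
                    f"{name}={getattr(self, name):g} s spans fewer than 3 "
                    f"frames at {self.frame_rate:g} fps; that phase is "
                    "effectively unresolved",
                    stacklevel=2,
                )

    @property
    def secondary_start(self) -> float:
        """Start of the secondary-rotation phase (plateau onset), s."""
        return self.omega_peak_time + self.omega_decay_duration

    @property
    def secondary_stop_width(self) -> float:
        return min(self.secondary_stop_duration, 0.5 * self.phase3_duration)

    @property
    def secondary_rate(self) -> float:
        """Plateau angular velocity of the secondary rotation, rad/s.

        Solved so the orientation change over the secondary phase
        (plateau plus final stop pulse) equals
        ``secondary_rotation_total`` exactly.
        """
        return self.secondary_rotation_total / (
            self.phase3_duration - 0.5 * self.secondary_stop_width
        )

    @property
    def total_duration(self) -> float:
        if self.duration is not None:
            return self.duration
        return self.secondary_start + self.phase3_duration


@dataclass(frozen=True)
class RaisedCosinePulse:
    """Acceleration pulse a(t) = A/2 * (1 - cos(2*pi*(t-t0)/w)) on [t0, t0+w].

    Zero with zero slope at both edges, hence C1 velocity when pulses
    are chained.  ``integral`` and ``double_integral`` are the exact
    cumulative velocity and displacement contributions from time 0
    (the pulse contributes nothing before t0 and coasts linearly in
    displacement after t0 + w).
    """

    amplitude: float
    t0: float
    width: float

    def value(self, t: np.ndarray) -> np.ndarray:
        tau = np.clip(np.asarray(t, dtype=float) - self.t0, 0.0, self.width)
        out = 0.5 * self.amplitude * (1.0 - np.cos(2.0 * np.pi * tau / self.width))
        return np.where((t >= self.t0) & (t <= self.t0 + self.width), out, 0.0)

    def integral(self, t: np.ndarray) -> np.ndarray:
        tau = np.clip(np.asarray(t, dtype=float) - self.t0, 0.0, self.width)
        w = self.width
        return 0.5 * self.amplitude * (
            tau - w / (2.0 * np.pi) * np.sin(2.0 * np.pi * tau / w)
        )

    def double_integral(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tau = np.clip(t - self.t0, 0.0, self.width)
        w = self.width
        inside = 0.5 * self.amplitude * (
            tau**2 / 2.0
            + (w / (2.0 * np.pi)) ** 2
            * (np.cos(2.0 * np.pi * tau / w) - 1.0)
        )
        # after the pulse the velocity contribution A*w/2 coasts
        after = np.clip(t - self.t0 - self.width, 0.0, None)
        return inside + 0.5 * self.amplitude * self.width * after

    @property
    def velocity_gain(self) -> float:
        """Net velocity change contributed by the full pulse."""
        return 0.5 * self.amplitude * self.width


@dataclass
class PoseTrajectory:
    """Sampled rigid-body pose with exact analytic derivatives.

    All series share ``times``; orientation is counter-clockwise
    positive in a right-handed, y-up frame.
    """

    times: np.ndarray
    centre: np.ndarray  # (N, 2) m
    theta: np.ndarray  # rad
    velocity: np.ndarray  # (N, 2) m/s
    acceleration: np.ndarray  # (N, 2) m/s^2
    omega: np.ndarray  # rad/s
    alpha: np.ndarray  # rad/s^2
    config: SimulationConfig | None = field(default=None, repr=False)

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=1)

    @property
    def accel_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.acceleration, axis=1)

    def phase3_rotation(self) -> float:
        """Exact (closed-form) orientation change over the secondary phase."""
        cfg = self.config
        if cfg is None:
            raise ValueError("trajectory has no attached config")
        pulses = _angular_pulses(cfg)

        def theta(t: float) -> float:
            return sum(float(p.double_integral(np.asarray([t]))[0]) for p in pulses)

        t0 = cfg.secondary_start
        return theta(t0 + cfg.phase3_duration) - theta(t0)


def _linear_pulses(cfg: SimulationConfig) -> list[RaisedCosinePulse]:
    """Vertical channel: accelerate over phase 1, decelerate to rest
    over phase 2 (net velocity change zero)."""
    t1, t2 = cfg.phase1_duration, cfg.phase2_duration
    up = RaisedCosinePulse(cfg.peak_linear_accel, 0.0, t1)
    down = RaisedCosinePulse(-cfg.peak_linear_accel * t1 / t2, t1, t2)
    return [up, down]


def _angular_pulses(cfg: SimulationConfig) -> list[RaisedCosinePulse]:
    """Angular channel, four raised-cosine acceleration pulses.

    A fast onset over the first half of the nominal primary window
    brings angular velocity to ``omega_onset_fraction`` of its peak
    (the impulsive shoulder rotation); a gentler approach pulse
    completes the rise at ``omega_peak_time``.  A decay pulse then
    hands over to the slow secondary-rotation plateau, whose rate is
    solved so the plateau-plus-stop angle equals
    ``secondary_rotation_total`` exactly; the stop pulse brings the
    rotation to rest at the catch.
    """
    t1, t2 = cfg.phase1_duration, cfg.phase2_duration
    w_peak = cfg.peak_angular_velocity_primary
    onset_w = 0.5 * t2
    onset_gain = cfg.omega_onset_fraction * w_peak
    approach_w = cfg.omega_peak_time - (t1 + onset_w)
    omega_sec = cfg.secondary_rate
    w_stop = cfg.secondary_stop_width
    t_end = cfg.secondary_start + cfg.phase3_duration
    return [
        RaisedCosinePulse(2.0 * onset_gain / onset_w, t1, onset_w),
        RaisedCosinePulse(
            2.0 * (w_peak - onset_gain) / approach_w, t1 + onset_w, approach_w
        ),
        RaisedCosinePulse(
            2.0 * (omega_sec - w_peak) / cfg.omega_decay_duration,
            cfg.omega_peak_time,
            cfg.omega_decay_duration,
        ),
        RaisedCosinePulse(-2.0 * omega_sec / w_stop, t_end - w_stop, w_stop),
    ]


def simulate_pose(config: SimulationConfig) -> PoseTrajectory:
    """Generate the deterministic ground-truth pose for a configuration.

    Returns closed-form position, velocity and acceleration series for
    the head centre and orientation; no randomness is involved.
    """
    n = int(round(config.total_duration * config.frame_rate)) + 1
    times = np.arange(n) / config.frame_rate

    lin = _linear_pulses(config)
    ang = _angular_pulses(config)

    ay = sum(p.value(times) for p in lin)
    vy = sum(p.integral(times) for p in lin)
    py = sum(p.double_integral(times) for p in lin)
    zeros = np.zeros_like(times)

    alpha = sum(p.value(times) for p in ang)
    omega = sum(p.integral(times) for p in ang)
    theta = sum(p.double_integral(times) for p in ang)

    return PoseTrajectory(
        times=times,
        centre=np.column_stack([zeros, py]),
        theta=np.asarray(theta),
        velocity=np.column_stack([zeros, vy]),
        acceleration=np.column_stack([zeros, ay]),
        omega=np.asarray(omega),
        alpha=np.asarray(alpha),
        config=config,
    )


def constant_rotation_pose(
    omega: float, duration: float, config: SimulationConfig | None = None
) -> PoseTrajectory:
    """Single-phase pose rotating at a fixed angular velocity.

    The centre is at rest and theta = omega * t; useful as an exact
    reference motion (orientation change is omega * duration
    identically).  ``config`` supplies frame rate, marker offsets and
    noise for projection; defaults are used when omitted.
    """
    if config is None:
        config = SimulationConfig()
    if duration <= 0:
        raise ConfigError("duration must be positive")
    n = int(round(duration * config.frame_rate)) + 1
    times = np.arange(n) / config.frame_rate
    zeros = np.zeros_like(times)
    zeros2 = np.zeros((n, 2))
    return PoseTrajectory(
        times=times,
        centre=zeros2.copy(),
        theta=omega * times,
        velocity=zeros2.copy(),
        acceleration=zeros2.copy(),
        omega=np.full(n, float(omega)),
        alpha=zeros,
        config=config,
    )


def _project(pose: PoseTrajectory, offset: np.ndarray) -> np.ndarray:
    c, s = np.cos(pose.theta), np.sin(pose.theta)
    ox, oy = offset
    return pose.centre + np.column_stack([c * ox - s * oy, s * ox + c * oy])


def project_markers(
    pose: PoseTrajectory, config: SimulationConfig | None = None
) -> TrackedPair:
    """Project the pose onto two noisy marker tracks.

    ``marker_i(t) = centre(t) + R(theta(t)) @ offset_i``, with iid
    Gaussian annotation noise (sd ``noise_sigma``) added independently
    per coordinate and per annotation repeat, seeded from the config.
    The returned pair holds the repeat-averaged tracks; the raw repeat
    tracks and the noiseless projections are preserved on the pair for
    oracle tests.
    """
    if config is None:
        config = pose.config
    if config is None:
        raise ConfigError("no configuration supplied")
    rng = np.random.default_rng(config.seed)
    repeats: list[MarkerTrack] = []
    noiseless: list[MarkerTrack] = []
    for marker_id, offset in zip((1, 2), config.marker_offsets):
        clean = _project(pose, np.asarray(offset, dtype=float))
        noiseless.append(
            MarkerTrack(marker_id, pose.times, clean[:, 0], clean[:, 1])
        )
        for rep in range(config.n_annotation_repeats):
            noisy = clean + rng.normal(
                0.0, config.noise_sigma, size=clean.shape
            )
            repeats.append(
                MarkerTrack(
                    marker_id, pose.times, noisy[:, 0], noisy[:, 1], repeat_id=rep
                )
            )
    by_marker = {
        m: [t for t in repeats if t.marker_id == m] for m in (1, 2)
    }
    pair = TrackedPair(
        track1=average_annotations(by_marker[1]),
        track2=average_annotations(by_marker[2]),
        frame_rate=config.frame_rate,
        repeat_tracks=repeats,
        noiseless=(noiseless[0], noiseless[1]),
    )
    return pair


def simulate_recording(config: SimulationConfig) -> tuple[PoseTrajectory, TrackedPair]:
    """Convenience: simulate the pose and project it in one call."""
    pose = simulate_pose(config)
    return pose, project_markers(pose, config)


def render_marker_mask(
    position: tuple[float, float],
    calibration: float,
    radius_px: int,
    shape: tuple[int, int] = (64, 64),
) -> np.ndarray:
    """Render a filled-disk binary mask for a marker position.

    ``position`` is in metres and mapped to pixel coordinates with
    ``calibration`` (m/px); pixel (x, y) maps to column x, row y.  A
    radius of 0 lights the single nearest pixel.  Fixture for centroid
    extraction; out-of-bounds positions are an error.
    """
    px = np.asarray(position, dtype=float) / calibration
    h, w = shape
    if not (0 <= px[0] <= w - 1 and 0 <= px[1] <= h - 1):
        raise ValueError(f"position maps to pixel {px}, outside {shape}")
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    if radius_px == 0:
        mask = np.zeros(shape, dtype=bool)
        mask[int(round(px[1])), int(round(px[0]))] = True
        return mask
    dist2 = (cols - px[0]) ** 2 + (rows - px[1]) ** 2
    return dist2 <= radius_px**2
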