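"""Impact energy and equal stress-equal velocity interspecies scaling.

The impact energy delivered by the pneumatic piston is kinetic,
E = 1/2 m v^2 with a 0.05 kg piston; measured piston velocities of
8.13 and 9.10 m/s correspond to the 1.7 J and 2.1 J energy levels.

Equal stress-equal velocity scaling converts rodent head kinematics to
human-equivalent values using the cube-root brain-mass ratio (13.8
mouse-to-human): rotational velocity is divided by the factor,
rotational acceleration by its square, and linear velocity is not
scaled.  Whether linear acceleration should be scaled is left
unscaled by default; all exponents are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .rigid_kinematics import KinematicSummary

__all__ = [
    "ImpactRecord",
    "ScalingRule",
    "impact_energy",
    "reported_energy",
    "scale_to_human",
    "batch_energy_check",
]

DEFAULT_PISTON_MASS = 0.05  # kg
DEFAULT_SCALING_FACTOR = 13.8  # cube-root mouse-to-human brain-mass ratio


def impact_energy(mass: float = DEFAULT_PISTON_MASS, velocity: float = 0.0) -> float:
    """Kinetic impact energy E = 1/2 m v^2, joules."""
    if mass <= 0:
        raise ValueError("piston mass must be positive")
    if velocity < 0:
        raise ValueError("velocity must be non-negative")
    return 0.5 * mass * velocity**2


def reported_energy(mass: float = DEFAULT_PISTON_MASS, velocity: float = 0.0) -> float:
    """Impact energy rounded to one decimal, the nominal label convention."""
    return round(impact_energy(mass, velocity), 1)


@dataclass(frozen=True)
class ImpactRecord:
    """One calibration impact: piston mass, measured velocity, energy."""

    measured_velocity: float  # m/s
    piston_mass: float = DEFAULT_PISTON_MASS  # kg
    nominal_energy_label: float | None = None  # J

    @property
    def energy(self) -> float:
        return impact_energy(self.piston_mass, self.measured_velocity)


@dataclass(frozen=True)
class ScalingRule:
    """Equal stress-equal velocity scaling rule.

    Each kinematic quantity is divided by ``factor ** exponent``;
    exponent 0 leaves the quantity unscaled.
    """

    factor: float = DEFAULT_SCALING_FACTOR
    exponents: dict = field(
        default_factory=lambda: {
            "angular_velocity": 1,
            "angular_acceleration": 2,
            "linear_velocity": 0,
            "linear_acceleration": 0,
        }
    )

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("scaling factor must be positive")
        for k, e in self.exponents.items():
            if not (isinstance(e, (int, np.integer)) and e >= 0):
                raise ValueError(f"exponent for {k} must be a non-negative integer")

    def divisor(self, quantity: str) -> float:
        return self.factor ** self.exponents.get(quantity, 0)

    def describe(self) -> str:
        parts = ", ".join(f"{k}/f^{e}" for k, e in sorted(self.exponents.items()))
        return f"equal-stress-equal-velocity f={self.factor} ({parts})"


def scale_to_human(
    summary: KinematicSummary, rule: ScalingRule = ScalingRule()
) -> KinematicSummary:
    """Convert a raw kinematic summary to human-equivalent values.

    Peak times are unchanged; the scaled summary records the rule
    applied and refuses to be scaled again.
    """
    if summary.scaled:
        raise ValueError(
            f"summary already scaled with rule {summary.scaling_rule!r}"
        )
    return replace(
        summary,
        peak_linear_accel_g=summary.peak_linear_accel_g
        / rule.divisor("linear_acceleration"),
        peak_linear_velocity=summary.peak_linear_velocity
        / rule.divisor("linear_velocity"),
        peak_angular_velocity=summary.peak_angular_velocity
        / rule.divisor("angular_velocity"),
        peak_angular_acceleration=summary.peak_angular_acceleration
        / rule.divisor("angular_acceleration"),
        scaled=True,
        scaling_rule=rule.describe(),
    )


def batch_energy_check(
    records: list[ImpactRecord],
    nominal: float,
    tolerance: float,
) -> dict:
    """Quality-control report for a set of calibration impacts.

    Each impact energy is compared against ``nominal +/- tolerance``;
    the report carries per-record energies, their mean, the
    coefficient of variation (sample sd / mean, percent; 0 for a
    single record) and an overall pass flag.
    """
    if not records:
        raise ValueError("no impact records supplied")
    energies = np.array([r.energy for r in records])
    passes = np.abs(energies - nominal) <= tolerance
    mean = float(energies.mean())
    cov = (
        float(100.0 * energies.std(ddof=1) / mean) if len(energies) > 1 else 0.0
    )
    return {
        "energies_J": energies.tolist(),
        "mean_J": mean,
        "cov_percent": cov,
        "nominal_J": nominal,
        "tolerance_J": tolerance,
        "record_pass": passes.tolist(),
        "all_pass": bool(passes.all()),
    }
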