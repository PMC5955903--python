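"""Group statistics and end-to-end pipeline orchestration.

Aggregates per-animal kinematic summaries into group statistics
(mean +/- SEM and coefficient of variation per peak metric) and runs
the whole pipeline — simulate or load recordings, analyze, summarize,
scale — writing CSV/JSON artifacts plus a run log with seeds,
parameters and input digests so any run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import rigid_kinematics, scaling, synthetic_data, tracking_io
from .rigid_kinematics import KinematicSeries, KinematicSummary, KinematicsConfig
from .scaling import ScalingRule
from .synthetic_data import SimulationConfig
from .tracking_io import TrackedPair

__all__ = [
    "GroupSummary",
    "PipelineConfig",
    "cov",
    "sem",
    "group_summary",
    "run_pipeline",
    "series_to_frame",
]

PEAK_METRICS = (
    "peak_linear_accel_g",
    "peak_linear_velocity",
    "peak_angular_velocity",
    "peak_angular_acceleration",
)


def cov(values) -> float:
    """Coefficient of variation, percent: 100 * sample sd / mean.

    Uses the (n-1)-denominator sample standard deviation; requires at
    least two values and a nonzero mean.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("coefficient of variation needs >= 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def sem(values) -> float:
    """Standard error of the mean, sample sd / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("SEM needs >= 2 values")
    return float(values.std(ddof=1) / math.sqrt(values.size))


@dataclass
class GroupSummary:
    """Mean +/- SEM and CoV of each peak metric over a group of animals."""

    label: str
    n: int
    scaled: bool
    metrics: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "scaled": self.scaled,
            "metrics": self.metrics,
        }


def group_summary(
    summaries: list[KinematicSummary], label: str
) -> GroupSummary:
    """Aggregate per-animal summaries (all raw or all scaled) into group stats."""
    if len(summaries) < 2:
        raise ValueError("group statistics need >= 2 animals")
    flags = {s.scaled for s in summaries}
    if len(flags) > 1:
        raise ValueError("cannot mix raw and human-scaled summaries in one group")
    metrics: dict[str, dict[str, float]] = {}
    for name in PEAK_METRICS:
        values = np.array([getattr(s, name) for s in summaries], dtype=float)
        mean = float(values.mean())
        metrics[name] = {
            "n": len(values),
            "mean": mean,
            "sem": sem(values),
            "cov_percent": cov(values) if mean != 0 else float("nan"),
        }
    return GroupSummary(label=label, n=len(summaries), scaled=flags.pop(), metrics=metrics)


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    """End-to-end run specification.

    Either ``input_dir`` points at recorded track CSV/JSON pairs
    (``*_tracks.csv`` + ``*_meta.json``), or ``groups`` describes
    simulated cohorts: a list of ``{"label": str, "energy_J": float,
    "n_animals": int, "sim": {SimulationConfig overrides}}``.
    Per-animal seeds are derived deterministically from ``seed``.
    """

    out_dir: str | Path = "impactkin_out"
    seed: int = 0
    input_dir: str | Path | None = None
    groups: list[dict] = field(default_factory=list)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    scaling_rule: ScalingRule = field(default_factory=ScalingRule)
    write_tracks: bool = True

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kin = KinematicsConfig(**raw.get("kinematics", {}))
        sc = raw.get("scaling", {})
        rule = ScalingRule(**sc) if sc else ScalingRule()
        return cls(
            out_dir=raw.get("out_dir", "impactkin_out"),
            seed=int(raw.get("seed", 0)),
            input_dir=raw.get("input_dir"),
            groups=raw.get("groups", []),
            kinematics=kin,
            scaling_rule=rule,
            write_tracks=bool(raw.get("write_tracks", True)),
        )


def _child_seed(root_seed: int, group_idx: int, animal_idx: int) -> int:
    ss = np.random.SeedSequence([root_seed, group_idx, animal_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def series_to_frame(series: KinematicSeries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": series.times,
            "v1x": series.v1[:, 0],
            "v1y": series.v1[:, 1],
            "v2x": series.v2[:, 0],
            "v2y": series.v2[:, 1],
            "speed_m_s": series.head_speed,
            "accel_g": series.head_accel_g,
            "omega_raw_rad_s": series.omega_raw,
            "omega_filt_rad_s": series.omega_filtered,
            "alpha_rad_s2": series.alpha,
            "alpha_unfiltered_rad_s2": series.alpha_unfiltered,
        }
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _simulated_pairs(config: PipelineConfig):
    for g_idx, group in enumerate(config.groups):
        label = group.get("label", f"group{g_idx}")
        for a_idx in range(int(group.get("n_animals", 1))):
            sim_kwargs = dict(group.get("sim", {}))
            sim_kwargs["seed"] = _child_seed(config.seed, g_idx, a_idx)
            sim = SimulationConfig(**sim_kwargs)
            _, pair = synthetic_data.simulate_recording(sim)
            pair.animal_id = f"{label}_a{a_idx:02d}"
            pair.energy_label_J = group.get("energy_J")
            yield label, pair, sim

def _loaded_pairs(config: PipelineConfig):
    input_dir = Path(config.input_dir)
    csvs = sorted(input_dir.glob("*_tracks.csv"))
    if not csvs:
        raise FileNotFoundError(f"no *_tracks.csv recordings in {input_dir}")
    for csv_path in csvs:
        meta_path = csv_path.with_name(
            csv_path.name.replace("_tracks.csv", "_meta.json")
        )
        pair = tracking_io.load_pair(csv_path, meta_path)
        label = (
            f"{pair.energy_label_J}J" if pair.energy_label_J is not None else "all"
        )
        yield label, pair, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate/load -> analyze -> summarize -> scale, writing artifacts.

    Returns the run log (also written to ``run_log.json``), which
    records the seed, every derived per-animal seed, all parameters
    and SHA-256 digests of the track files, making re-runs
    byte-reproducible.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    source = _loaded_pairs(config) if config.input_dir else _simulated_pairs(config)

    by_group: dict[str, list[KinematicSummary]] = {}
    log: dict = {
        "seed": config.seed,
        "kinematics": vars(config.kinematics).copy(),
        "scaling": {
            "factor": config.scaling_rule.factor,
            "exponents": dict(config.scaling_rule.exponents),
        },
        "animals": [],
    }
    for label, pair, sim in source:
        series, summ = rigid_kinematics.analyze_pair(pair, config.kinematics)
        by_group.setdefault(label, []).append(summ)
        stem = out / pair.animal_id
        series_to_frame(series).to_csv(
            f"{stem}_series.csv", index=False, float_format="%.17g"
        )
        _write_json(summ.to_dict(), Path(f"{stem}_summary.json"))
        entry: dict = {"animal_id": pair.animal_id, "group": label}
        if sim is not None:
            entry["sim_seed"] = sim.seed
            entry["noise_sigma"] = sim.noise_sigma
        if config.write_tracks and pair.repeat_tracks:
            tracks_path = Path(f"{stem}_tracks.csv")
            tracking_io.write_pair(
                pair, tracks_path, Path(f"{stem}_meta.json")
            )
            entry["tracks_sha256"] = _sha256(tracks_path)
        log["animals"].append(entry)

    groups_out: dict = {}
    scaled_out: dict = {}
    for label, summaries in by_group.items():
        if len(summaries) >= 2:
            groups_out[label] = group_summary(summaries, label).to_dict()
            scaled = [
                scaling.scale_to_human(s, config.scaling_rule) for s in summaries
            ]
            scaled_out[label] = group_summary(scaled, label).to_dict()
    _write_json(groups_out, out / "group_summary.json")
    _write_json(scaled_out, out / "group_summary_scaled.json")
    _write_json(log, out / "run_log.json")
    return log
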