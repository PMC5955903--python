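"""Marker-track containers, CSV I/O, calibration and annotation averaging.

Tracks originate as manually annotated marker positions on high-speed
video frames.  Each marker is annotated several times independently
("annotation repeats"); the repeats are averaged before any kinematic
computation.  Coordinates may arrive in pixels (with a pixel-to-metre
calibration pending) or already in metres.

CSV track dialect: comma-separated, UTF-8, '.' decimal, mandatory header
``frame,time_s,marker_id,repeat_id,x,y``.  One row per (frame, marker,
repeat).  Frames must be consecutive integers within a repeat and the
time base must be uniform.  A JSON sidecar carries per-recording
metadata (frame_rate, calibration, energy label, animal id, y-axis
convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerTrack",
    "TrackedPair",
    "TrackFormatError",
    "read_tracks",
    "write_tracks",
    "write_pair",
    "load_pair",
    "build_pair",
    "centroid",
    "average_annotations",
    "calibrate",
    "read_metadata",
    "write_metadata",
]

TRACK_COLUMNS = ["frame", "time_s", "marker_id", "repeat_id", "x", "y"]

#: relative tolerance on time-base uniformity (seconds)
TIME_UNIFORMITY_TOL = 1e-9


class TrackFormatError(ValueError):
    """Raised when a track file violates the CSV track dialect."""


@dataclass
class MarkerTrack:
    """Time series of one marker's 2D coordinates.

    Parameters
    ----------
    marker_id : int
        Marker label (1 or 2 for a tracked pair).
    times : ndarray, s
        Uniformly spaced sample times.
    x, y : ndarray
        Coordinates, metres once calibrated (pixels before).
    repeat_id : int or None
        Annotation-repeat index; ``None`` after repeat averaging.
    units : str
        ``"m"`` or ``"px"``.
    """

    marker_id: int
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    repeat_id: int | None = None
    units: str = "m"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise TrackFormatError("times, x and y must have equal length")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise TrackFormatError("times must be strictly increasing")
            if np.ptp(dt) > TIME_UNIFORMITY_TOL:
                raise TrackFormatError(
                    f"non-uniform time base (spread {np.ptp(dt):.3e} s)"
                )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of (x, y) coordinates."""
        return np.column_stack([self.x, self.y])

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ValueError("need >=2 samples for a sampling interval")
        return float(self.times[1] - self.times[0])


@dataclass
class TrackedPair:
    """Two repeat-averaged rigid markers for one recording.

    ``delta`` is the relative position of marker 1 with respect to
    marker 2, the lever arm of the rigid-body angular-velocity
    estimator.
    """

    track1: MarkerTrack
    track2: MarkerTrack
    frame_rate: float
    animal_id: str = "unknown"
    energy_label_J: float | None = None
    calibration_m_per_px: float | None = None
    repeat_tracks: list[MarkerTrack] | None = field(default=None, repr=False)
    noiseless: tuple[MarkerTrack, MarkerTrack] | None = field(
        default=None, repr=False
    )

    def __post_init__(self) -> None:
        if len(self.track1) != len(self.track2):
            raise TrackFormatError("paired tracks must share the time base")
        if not np.allclose(
            self.track1.times, self.track2.times, atol=TIME_UNIFORMITY_TOL
        ):
            raise TrackFormatError("paired tracks must share the time base")

    def __len__(self) -> int:
        return len(self.track1)

    @property
    def times(self) -> np.ndarray:
        return self.track1.times

    @property
    def delta(self) -> np.ndarray:
        """(N, 2) relative position p1 - p2, metres."""
        return self.track1.positions - self.track2.positions

    @property
    def separation(self) -> np.ndarray:
        """Per-frame inter-marker distance, metres."""
        return np.linalg.norm(self.delta, axis=1)


# ---------------------------------------------------------------------------
# CSV I/O


def read_tracks(
    path: str | Path,
    *,
    calibration: float | None = None,
    y_down: bool = False,
) -> list[MarkerTrack]:
    """Read marker tracks from a track-dialect CSV.

    Parameters
    ----------
    calibration : float, optional
        Metres per pixel.  When given, coordinates are converted to
        metres; otherwise they are kept as read and flagged ``px``
        (conventionally the file stores pixels in that case).
    y_down : bool
        If True the file uses the image convention (y grows downward);
        the y axis is flipped to y-up on ingestion.

    Returns
    -------
    list of MarkerTrack, one per (marker, repeat), sorted by
    (marker_id, repeat_id).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing columns {missing}")

    dup = df.duplicated(subset=["frame", "marker_id", "repeat_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise TrackFormatError(
            f"{path}: duplicate (frame, marker, repeat) at data row {row}"
        )

    tracks: list[MarkerTrack] = []
    for (marker_id, repeat_id), grp in df.groupby(["marker_id", "repeat_id"]):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(frames[0], frames[0] + len(frames))):
            gap = int(frames[np.flatnonzero(np.diff(frames) != 1)[0]])
            raise TrackFormatError(
                f"{path}: gap in frame numbering after frame {gap} "
                f"(marker {marker_id}, repeat {repeat_id})"
            )
        x = grp["x"].to_numpy(dtype=float)
        y = grp["y"].to_numpy(dtype=float)
        if y_down:
            y = -y
        if calibration is not None:
            x = x * calibration
            y = y * calibration
        try:
            track = MarkerTrack(
                marker_id=int(marker_id),
                times=grp["time_s"].to_numpy(dtype=float),
                x=x,
                y=y,
                repeat_id=int(repeat_id),
                units="m" if calibration is not None else "px",
            )
        except TrackFormatError as exc:
            raise TrackFormatError(
                f"{path}: marker {marker_id}, repeat {repeat_id}: {exc}"
            ) from exc
        tracks.append(track)
    tracks.sort(key=lambda t: (t.marker_id, t.repeat_id or 0))
    return tracks


def write_tracks(tracks: Sequence[MarkerTrack], path: str | Path) -> None:
    """Write tracks to the CSV track dialect (full float precision)."""
    frames_dfs = []
    for t in tracks:
        frames_dfs.append(
            pd.DataFrame(
                {
                    "frame": np.arange(len(t)),
                    "time_s": t.times,
                    "marker_id": t.marker_id,
                    "repeat_id": t.repeat_id if t.repeat_id is not None else 0,
                    "x": t.x,
                    "y": t.y,
                }
            )
        )
    df = pd.concat(frames_dfs, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.17g")


def write_metadata(pair: TrackedPair, path: str | Path) -> None:
    meta = {
        "animal_id": pair.animal_id,
        "frame_rate": pair.frame_rate,
        "calibration_m_per_px": pair.calibration_m_per_px,
        "energy_label_J": pair.energy_label_J,
        "y_axis": "up",
    }
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_metadata(path: str | Path) -> dict:
    meta = json.loads(Path(path).read_text())
    if "frame_rate" not in meta:
        raise TrackFormatError(f"{path}: metadata missing 'frame_rate'")
    return meta


def write_pair(pair: TrackedPair, csv_path: str | Path, meta_path: str | Path) -> None:
    """Write a recording: repeat tracks if present, else the averaged pair."""
    tracks = pair.repeat_tracks or [pair.track1, pair.track2]
    write_tracks(tracks, csv_path)
    write_metadata(pair, meta_path)


def load_pair(csv_path: str | Path, meta_path: str | Path) -> TrackedPair:
    """Load a recording from a track CSV plus its JSON sidecar.

    Repeats are averaged per marker; pixel coordinates are converted
    with the sidecar calibration when present.
    """
    meta = read_metadata(meta_path)
    tracks = read_tracks(
        csv_path,
        calibration=meta.get("calibration_m_per_px"),
        y_down=meta.get("y_axis", "up") == "down",
    )
    return build_pair(
        tracks,
        frame_rate=float(meta["frame_rate"]),
        animal_id=meta.get("animal_id", "unknown"),
        energy_label_J=meta.get("energy_label_J"),
        calibration_m_per_px=meta.get("calibration_m_per_px"),
    )


def build_pair(
    tracks: Sequence[MarkerTrack],
    *,
    frame_rate: float,
    animal_id: str = "unknown",
    energy_label_J: float | None = None,
    calibration_m_per_px: float | None = None,
) -> TrackedPair:
    """Average annotation repeats and assemble a TrackedPair."""
    by_marker: dict[int, list[MarkerTrack]] = {}
    for t in tracks:
        by_marker.setdefault(t.marker_id, []).append(t)
    if sorted(by_marker) != [1, 2]:
        raise TrackFormatError(
            f"expected markers {{1, 2}}, found {sorted(by_marker)}"
        )
    avg = {m: average_annotations(reps) for m, reps in by_marker.items()}
    return TrackedPair(
        track1=avg[1],
        track2=avg[2],
        frame_rate=frame_rate,
        animal_id=animal_id,
        energy_label_J=energy_label_J,
        calibration_m_per_px=calibration_m_per_px,
        repeat_tracks=list(tracks),
    )


# ---------------------------------------------------------------------------
# Centroid extraction (mask fixtures)


def centroid(mask: np.ndarray) -> tuple[float, float]:
    """Arithmetic-mean centroid of the true pixels of a binary mask.

    Returns ``(x, y)`` with x the column index and y the row index,
    matching the (x, y) ordering of marker coordinates.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask has no centroid")
    return float(cols.mean()), float(rows.mean())


# ---------------------------------------------------------------------------
# Annotation averaging and calibration


def average_annotations(tracks: Sequence[MarkerTrack]) -> MarkerTrack:
    """Per-frame arithmetic mean of annotation repeats of one marker.

    The manual isolation of each marker is repeated independently
    several times per video; averaging the repeats suppresses
    annotation noise by ~1/sqrt(n_repeats).
    """
    if len(tracks) == 0:
        raise ValueError("no repeats to average")
    # sort by repeat id so the float summation order (hence the result,
    # bit for bit) is independent of input ordering
    tracks = sorted(tracks, key=lambda t: (t.repeat_id is None, t.repeat_id))
    first = tracks[0]
    for t in tracks[1:]:
        if len(t) != len(first):
            raise TrackFormatError("annotation repeats have mismatched lengths")
        if t.marker_id != first.marker_id:
            raise TrackFormatError("cannot average repeats of different markers")
        if not np.allclose(t.times, first.times, atol=TIME_UNIFORMITY_TOL):
            raise TrackFormatError("annotation repeats must share the time base")
    x = np.mean([t.x for t in tracks], axis=0)
    y = np.mean([t.y for t in tracks], axis=0)
    return MarkerTrack(
        marker_id=first.marker_id,
        times=first.times.copy(),
        x=x,
        y=y,
        repeat_id=None,
        units=first.units,
    )


def calibrate(
    tracks: Sequence[MarkerTrack], known_separation: float
) -> tuple[list[MarkerTrack], float]:
    """Scale pixel tracks to metres from a known marker separation.

    The scale is ``known_separation / median per-frame inter-marker
    distance``; the median is robust to annotation outliers.  The same
    scale is applied to both axes of every input track (a pure
    similarity scaling).

    Returns the calibrated tracks and the scale (m/px).  Calling again
    on already-calibrated tracks with the same separation yields a
    scale of 1, so the operation is idempotent.
    """
    if known_separation <= 0:
        raise ValueError("known_separation must be positive")
    by_marker: dict[int, list[MarkerTrack]] = {}
    for t in tracks:
        by_marker.setdefault(t.marker_id, []).append(t)
    if len(by_marker) != 2:
        raise ValueError("calibration needs exactly two markers")
    m_lo, m_hi = sorted(by_marker)
    p1 = average_annotations(by_marker[m_lo]).positions
    p2 = average_annotations(by_marker[m_hi]).positions
    sep = np.linalg.norm(p1 - p2, axis=1)
    med = float(np.median(sep))
    if med == 0:
        raise ValueError("zero median marker separation; cannot calibrate")
    scale = known_separation / med
    out = [
        replace(t, x=t.x * scale, y=t.y * scale, units="m") for t in tracks
    ]
    return out, scale
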