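"""Velocity-threshold identification (I-VT) of fixations and saccades.

Gaze is recorded as a stream of time-stamped unit direction vectors (nominal
120 Hz from an HMD eye tracker).  Angular velocity between consecutive
samples is the angle between the two direction vectors divided by the
timestamp difference.  Sample pairs are labelled fixation when the velocity
is below ``v_fix_max`` (default 30 deg/s), saccade when it exceeds
``v_sac_min`` (default 60 deg/s), and unclassified in the gap between the
two thresholds.  Maximal runs of identical labels become candidate events,
which are kept only if their duration falls inside kind-specific windows
(fixation 100-500 ms, saccade 30-80 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FIXATION = "fixation"
SACCADE = "saccade"
UNCLASSIFIED = "unclassified"


class InvalidInputError(ValueError):
    pass


class OrderingError(ValueError):
    """Timestamps not strictly increasing."""


@dataclass(frozen=True)
class ThresholdConfig:
    """I-VT detection thresholds.

    Velocities in deg/s, durations in seconds.  Defaults follow thresholds
    validated for HMD eye tracking, where head motion adds noise.
    """

    v_fix_max: float = 30.0
    v_sac_min: float = 60.0
    fix_dur_min: float = 0.100
    fix_dur_max: float = 0.500
    sac_dur_min: float = 0.030
    sac_dur_max: float = 0.080
    # inter-sample gaps larger than this multiple of the median interval
    # terminate any open run (blink / dropout guard)
    gap_factor: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.v_fix_max <= self.v_sac_min):
            raise InvalidInputError(
                f"require 0 < v_fix_max <= v_sac_min, got "
                f"{self.v_fix_max}, {self.v_sac_min}"
            )
        if not (0 < self.fix_dur_min < self.fix_dur_max):
            raise InvalidInputError("invalid fixation duration window")
        if not (0 < self.sac_dur_min < self.sac_dur_max):
            raise InvalidInputError("invalid saccade duration window")

    def duration_window(self, kind: str) -> tuple[float, float]:
        if kind == FIXATION:
            return self.fix_dur_min, self.fix_dur_max
        if kind == SACCADE:
            return self.sac_dur_min, self.sac_dur_max
        raise InvalidInputError(f"unknown event kind {kind!r}")


@dataclass
class GazeStream:
    """Time-stamped gaze directions with optional eye/head origins.

    ``t``: (n,) seconds, strictly increasing.  ``dirs``: (n, 3) direction
    vectors, renormalized on construction.  ``origins``: (n, 3) scene-unit
    positions of the eye (defaults to the scene origin).
    """

    t: np.ndarray
    dirs: np.ndarray
    origins: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dirs = np.asarray(self.dirs, dtype=float)
        if self.t.ndim != 1 or self.dirs.shape != (self.t.size, 3):
            raise InvalidInputError("t must be (n,), dirs must be (n, 3)")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise OrderingError("timestamps must be strictly increasing")
        norms = np.linalg.norm(self.dirs, axis=1)
        if np.any(norms == 0) or not np.all(np.isfinite(self.dirs)):
            raise InvalidInputError("gaze directions must be finite and nonzero")
        self.dirs = self.dirs / norms[:, None]
        if self.origins is None:
            self.origins = np.zeros_like(self.dirs)
        else:
            self.origins = np.asarray(self.origins, dtype=float)
            if self.origins.shape != self.dirs.shape:
                raise InvalidInputError("origins must match dirs shape")

    def __len__(self) -> int:
        return self.t.size

    @classmethod
    def from_csv(cls, path: str | Path) -> "GazeStream":
        df = pd.read_csv(path, comment="#")
        required = ["timestamp_s", "dir_x", "dir_y", "dir_z"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise InvalidInputError(f"gaze CSV missing columns {missing}")
        origins = None
        if {"origin_x", "origin_y", "origin_z"} <= set(df.columns):
            origins = df[["origin_x", "origin_y", "origin_z"]].to_numpy()
        return cls(
            t=df["timestamp_s"].to_numpy(),
            dirs=df[["dir_x", "dir_y", "dir_z"]].to_numpy(),
            origins=origins,
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "timestamp_s": self.t,
                "dir_x": self.dirs[:, 0],
                "dir_y": self.dirs[:, 1],
                "dir_z": self.dirs[:, 2],
                "origin_x": self.origins[:, 0],
                "origin_y": self.origins[:, 1],
                "origin_z": self.origins[:, 2],
            }
        )
        df.to_csv(path, index=False, float_format="%.6f")


@dataclass
class RawEvent:
    """A maximal run of identically-labelled sample pairs (pre-validation)."""

    kind: str
    t_start: float
    t_end: float
    sample_span: tuple[int, int]  # [start, stop) indices into the sample stream

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class GazeEvent:
    """A validated fixation or saccade."""

    kind: str
    t_start: float
    t_end: float
    sample_span: tuple[int, int]
    mean_dir: np.ndarray
    aoi_id: str = field(default="none")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def angular_difference(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two gaze direction vectors, in degrees.

    Inputs are defensively renormalized; the dot product is clamped to
    [-1, 1] before the arccos, so the result is always in [0, 180].
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0 or not (np.isfinite(n1) and np.isfinite(n2)):
        raise InvalidInputError("gaze vectors must be finite and nonzero")
    cosang = np.clip(np.dot(v1 / n1, v2 / n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def gaze_velocity(dtheta: float, dt: float) -> float:
    """Angular gaze velocity v = dtheta / dt, in deg/s.  Requires dt > 0."""
    if dt <= 0:
        raise InvalidInputError(f"inter-sample interval must be positive, got {dt}")
    return dtheta / dt


def velocity_series(stream: GazeStream) -> pd.DataFrame:
    """Per-pair angular differences and velocities.

    Returns a DataFrame with one row per consecutive sample pair: ``t`` (time
    of the later sample), ``dtheta`` (deg), ``dt`` (s), ``v`` (deg/s).
    """
    if len(stream) < 2:
        raise InvalidInputError("need at least 2 samples")
    dots = np.einsum("ij,ij->i", stream.dirs[:-1], stream.dirs[1:])
    dtheta = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
    dt = np.diff(stream.t)
    return pd.DataFrame(
        {"t": stream.t[1:], "dtheta": dtheta, "dt": dt, "v": dtheta / dt}
    )


def classify_samples(stream: GazeStream, cfg: ThresholdConfig | None = None) -> np.ndarray:
    """Label each consecutive sample pair fixation / saccade / unclassified.

    fixation iff v < v_fix_max; saccade iff v > v_sac_min; the band in
    between is left unclassified (it terminates runs downstream).
    """
    cfg = cfg or ThresholdConfig()
    vel = velocity_series(stream)
    labels = np.full(len(vel), UNCLASSIFIED, dtype=object)
    labels[vel["v"].to_numpy() < cfg.v_fix_max] = FIXATION
    labels[vel["v"].to_numpy() > cfg.v_sac_min] = SACCADE
    return labels


def segment_events(
    labels: np.ndarray,
    times: np.ndarray,
    gap_factor: float = 3.0,
) -> list[RawEvent]:
    """Group maximal runs of identical non-unclassified pair labels.

    ``labels`` has one entry per consecutive sample pair; ``times`` are the
    n = len(labels) + 1 sample timestamps.  Unclassified pairs terminate any
    open run, as do inter-sample gaps exceeding ``gap_factor`` times the
    median sampling interval (blinks / dropouts).
    """
    labels = np.asarray(labels, dtype=object)
    times = np.asarray(times, dtype=float)
    if times.size != labels.size + 1:
        raise InvalidInputError("times must have one more entry than labels")
    if labels.size == 0:
        return []
    dt = np.diff(times)
    gap = dt > gap_factor * np.median(dt)

    events: list[RawEvent] = []
    run_start: int | None = None
    run_kind: str | None = None

    def close(run_start: int, stop_pair: int) -> None:
        # pairs run_start..stop_pair-1 cover samples run_start..stop_pair
        events.append(
            RawEvent(
                kind=run_kind,
                t_start=times[run_start],
                t_end=times[stop_pair],
                sample_span=(run_start, stop_pair + 1),
            )
        )

    for i, lab in enumerate(labels):
        breaks = lab == UNCLASSIFIED or gap[i]
        if run_start is not None and (breaks or lab != run_kind):
            close(run_start, i)
            run_start, run_kind = None, None
        if not breaks and run_start is None:
            run_start, run_kind = i, lab
    if run_start is not None:
        close(run_start, labels.size)
    return events


def validate_events(
    raw: list[RawEvent],
    cfg: ThresholdConfig | None = None,
    stream: GazeStream | None = None,
) -> list[GazeEvent]:
    """Keep candidates whose duration lies inside the kind-specific window.

    Candidates outside the window are discarded entirely (the duration gates
    act as validity filters, not segmentation rules).  If ``stream`` is
    given, each event's mean gaze direction is attached.
    """
    cfg = cfg or ThresholdConfig()
    out: list[GazeEvent] = []
    for ev in raw:
        lo, hi = cfg.duration_window(ev.kind)
        if lo <= ev.duration <= hi:
            if stream is not None:
                d = stream.dirs[ev.sample_span[0] : ev.sample_span[1]].mean(axis=0)
                mean_dir = d / np.linalg.norm(d)
            else:
                mean_dir = np.full(3, np.nan)
            out.append(
                GazeEvent(
                    kind=ev.kind,
                    t_start=ev.t_start,
                    t_end=ev.t_end,
                    sample_span=ev.sample_span,
                    mean_dir=mean_dir,
                )
            )
    return out


def detect_events(
    stream: GazeStream, cfg: ThresholdConfig | None = None
) -> list[GazeEvent]:
    """Full I-VT pipeline: velocities -> labels -> runs -> duration gates."""
    cfg = cfg or ThresholdConfig()
    labels = classify_samples(stream, cfg)
    raw = segment_events(labels, stream.t, gap_factor=cfg.gap_factor)
    return validate_events(raw, cfg, stream)


def events_to_frame(events: list[GazeEvent]) -> pd.DataFrame:
    """Event table with times in seconds and durations in milliseconds."""
    return pd.DataFrame(
        {
            "kind": [e.kind for e in events],
            "t_start_s": [e.t_start for e in events],
            "t_end_s": [e.t_end for e in events],
            "duration_ms": [1e3 * e.duration for e in events],
            "aoi_id": [e.aoi_id for e in events],
        }
    )


def write_events_csv(events: list[GazeEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False, float_format="%.6f")
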