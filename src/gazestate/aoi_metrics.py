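"""Area-of-interest (AOI) ray intersection and eye-tracking metric streams.

In the original VR system, gaze rays were cast against scene colliders
(Unity raycast) to decide which object — an organelle of the animal-cell
model — the learner was looking at.  Here the colliders are analytic
spheres and axis-aligned boxes; gaze events are attributed to the AOI hit
by the majority of their samples' rays, and four cumulative metrics
(fixation duration/count, saccade duration/count) are accumulated per AOI
on a fixed emission grid and written as time-series CSV.

Scene units are meters; the coordinate system is right-handed.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from gazestate.gaze_events import FIXATION, SACCADE, GazeEvent, GazeStream


class AOIConfigError(ValueError):
    pass


class MetricsParseError(ValueError):
    pass


@dataclass(frozen=True)
class AOIDefinition:
    """One scene area of interest: a sphere or an axis-aligned box.

    ``size`` is the radius for spheres and the (3,) half-extent vector for
    boxes, in scene units (meters).
    """

    aoi_id: str
    shape: str  # "sphere" | "box"
    center: tuple[float, float, float]
    size: float | tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "box"):
            raise AOIConfigError(f"unknown AOI shape {self.shape!r}")
        if self.shape == "sphere":
            if not np.isscalar(self.size) or self.size <= 0:
                raise AOIConfigError(f"sphere radius must be positive, got {self.size}")
        else:
            he = np.asarray(self.size, dtype=float)
            if he.shape != (3,) or np.any(he <= 0):
                raise AOIConfigError("box half-extents must be 3 positive values")


def load_aois(path: str | Path) -> list[AOIDefinition]:
    """Read AOI definitions from a JSON list.

    Sphere entries: ``{"aoi_id", "shape": "sphere", "center", "radius"}``;
    box entries use ``"half_extents"`` instead of ``"radius"``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    aois = []
    ids = set()
    for entry in raw:
        size = entry["radius"] if entry["shape"] == "sphere" else tuple(entry["half_extents"])
        aoi = AOIDefinition(
            aoi_id=entry["aoi_id"],
            shape=entry["shape"],
            center=tuple(entry["center"]),
            size=size,
        )
        if aoi.aoi_id in ids:
            raise AOIConfigError(f"duplicate aoi_id {aoi.aoi_id!r}")
        ids.add(aoi.aoi_id)
        aois.append(aoi)
    return aois


def save_aois(aois: list[AOIDefinition], path: str | Path) -> None:
    entries = []
    for a in aois:
        e: dict = {"aoi_id": a.aoi_id, "shape": a.shape, "center": list(a.center)}
        if a.shape == "sphere":
            e["radius"] = a.size
        else:
            e["half_extents"] = list(a.size)
        entries.append(e)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2)


def ray_aoi_intersect(
    origin: np.ndarray, direction: np.ndarray, aoi: AOIDefinition
) -> tuple[bool, float]:
    """Nearest non-negative intersection of a gaze ray with an AOI.

    Returns ``(hit, distance)``; distance is NaN on a miss.  Spheres use the
    quadratic discriminant; boxes use the slab method.  Rays starting inside
    the volume hit at distance 0 (gaze from within the collider counts as a
    collision, as in the original raycast system).
    """
    origin = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    center = np.asarray(aoi.center, dtype=float)

    if aoi.shape == "sphere":
        oc = origin - center
        b = float(np.dot(oc, d))
        c = float(np.dot(oc, oc)) - float(aoi.size) ** 2
        disc = b * b - c
        if disc < 0:
            return False, float("nan")
        sq = np.sqrt(disc)
        t0, t1 = -b - sq, -b + sq
        if t1 < 0:
            return False, float("nan")
        return True, float(max(t0, 0.0))

    # axis-aligned box, slab method
    he = np.asarray(aoi.size, dtype=float)
    lo, hi = center - he, center + he
    t_near, t_far = -np.inf, np.inf
    for k in range(3):
        if d[k] == 0.0:
            if origin[k] < lo[k] or origin[k] > hi[k]:
                return False, float("nan")
            continue
        ta = (lo[k] - origin[k]) / d[k]
        tb = (hi[k] - origin[k]) / d[k]
        if ta > tb:
            ta, tb = tb, ta
        t_near = max(t_near, ta)
        t_far = min(t_far, tb)
    if t_near > t_far or t_far < 0:
        return False, float("nan")
    return True, float(max(t_near, 0.0))


def _first_hit(origin: np.ndarray, direction: np.ndarray, aois: list[AOIDefinition]) -> str:
    """aoi_id of the nearest AOI hit by this ray, or 'none'."""
    best_id, best_t = "none", np.inf
    for aoi in aois:
        hit, t = ray_aoi_intersect(origin, direction, aoi)
        if hit and t < best_t:
            best_id, best_t = aoi.aoi_id, t
    return best_id


def attribute_events(
    events: list[GazeEvent],
    stream: GazeStream,
    aois: list[AOIDefinition],
) -> list[GazeEvent]:
    """Attribute each event to the AOI hit by the majority of its samples.

    Every sample ray inside the event's span is cast against all AOIs and
    the per-sample nearest hits are tallied; 'none' (no hit) rays do not
    vote unless no ray hits anything.  Ties break by earliest hit within
    the event.  Events are modified in place and returned.
    """
    for ev in events:
        i0, i1 = ev.sample_span
        hits = [
            _first_hit(stream.origins[i], stream.dirs[i], aois) for i in range(i0, i1)
        ]
        tally = Counter(h for h in hits if h != "none")
        if not tally:
            ev.aoi_id = "none"
            continue
        top = max(tally.values())
        winners = {a for a, c in tally.items() if c == top}
        if len(winners) == 1:
            ev.aoi_id = winners.pop()
        else:
            ev.aoi_id = next(h for h in hits if h in winners)
    return events


def accumulate_metrics(
    events: list[GazeEvent],
    aois: list[AOIDefinition],
    t_end: float,
    grid_rate: float = 10.0,
    t_start: float = 0.0,
) -> pd.DataFrame:
    """Cumulative per-AOI metric time series on a fixed emission grid.

    Each completed event adds its full duration (seconds) and one count to
    its AOI's running totals at the event's end time; one row per grid tick
    per AOI is emitted.  Events attributed to 'none' are not accumulated.

    Columns: ``timestamp_s, aoi_id, fixation_duration_s, fixation_count,
    saccade_duration_s, saccade_count``.
    """
    if grid_rate <= 0:
        raise AOIConfigError("grid_rate must be positive")
    ticks = np.arange(t_start, t_end + 0.5 / grid_rate, 1.0 / grid_rate)
    rows = []
    per_aoi = {
        a.aoi_id: sorted(
            (e for e in events if e.aoi_id == a.aoi_id), key=lambda e: e.t_end
        )
        for a in aois
    }
    for aoi_id, evs in per_aoi.items():
        ends = np.array([e.t_end for e in evs])
        is_fix = np.array([e.kind == FIXATION for e in evs], dtype=bool)
        durs = np.array([e.duration for e in evs])
        for tk in ticks:
            done = ends <= tk
            rows.append(
                {
                    "timestamp_s": tk,
                    "aoi_id": aoi_id,
                    "fixation_duration_s": float(durs[done & is_fix].sum()),
                    "fixation_count": int((done & is_fix).sum()),
                    "saccade_duration_s": float(durs[done & ~is_fix].sum()),
                    "saccade_count": int((done & ~is_fix).sum()),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "timestamp_s",
            "aoi_id",
            "fixation_duration_s",
            "fixation_count",
            "saccade_duration_s",
            "saccade_count",
        ],
    )
    return df.sort_values(["timestamp_s", "aoi_id"], kind="stable").reset_index(drop=True)


METRIC_COLUMNS = [
    "timestamp_s",
    "aoi_id",
    "fixation_duration_s",
    "fixation_count",
    "saccade_duration_s",
    "saccade_count",
]


def write_metrics_csv(series: pd.DataFrame, path: str | Path) -> None:
    """Write a metric time series; floats at 6 decimals for round-tripping."""
    missing = [c for c in METRIC_COLUMNS if c not in series.columns]
    if missing:
        raise MetricsParseError(f"metric series missing columns {missing}")
    with open(path, "w") as fh:
        fh.write("# gazestate AOI metrics; scene units meters, right-handed axes\n")
        series[METRIC_COLUMNS].to_csv(fh, index=False, float_format="%.6f")


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    """Read a metric time series CSV, reporting malformed rows by line number."""
    try:
        df = pd.read_csv(path, comment="#")
    except (ValueError, pd.errors.ParserError) as exc:
        raise MetricsParseError(f"{path}: {exc}") from exc
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise MetricsParseError(f"{path}: missing columns {missing}")
    numeric = [c for c in METRIC_COLUMNS if c != "aoi_id"]
    vals = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = vals.isna().any(axis=1) | df["aoi_id"].isna()
    if bad.any():
        # +2 for the header row and 1-based numbering (+1 comment header line)
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 3
        raise MetricsParseError(f"{path}: malformed row at line {lineno}")
    out = df[METRIC_COLUMNS].copy()
    out[numeric] = vals
    out["fixation_count"] = out["fixation_count"].astype(int)
    out["saccade_count"] = out["saccade_count"].astype(int)
    return out
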