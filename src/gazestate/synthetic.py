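"""Synthetic gaze sessions calibrated to the study's printed statistics.

The participant dataset behind the study (26 learners x 3 induced states)
is not public, so every downstream stage is exercised on simulated data
with the same statistical structure:

* raw 120 Hz gaze streams built from alternating planted fixation/saccade
  segments (ground truth retained), suitable for I-VT recovery tests;
* per-session metric time series (100 steps at 10 Hz) whose final
  aggregates are drawn around the published per-state means/SDs with a
  shared per-participant random effect inducing within-subject correlation;
* questionnaire scale scores drawn the same way, truncated to scale bounds.

The generator is aggregate-level by design: the study reports only
means/SDs per state, so no cognitive mechanism is modelled.  All
randomness flows from one integer seed through named sub-streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from gazestate import reference_tables as ref
from gazestate.aoi_metrics import AOIDefinition
from gazestate.gaze_events import FIXATION, SACCADE, GazeStream


class SimulationConfigError(ValueError):
    pass


STATE_NAMES = {0: "overload", 1: "immersion", 2: "distraction"}

# organelles of the animal-cell scene, arranged 2 m from the viewer
ORGANELLES = (
    "nucleus",
    "cell_membrane",
    "cytoplasm",
    "endoplasmic_reticulum",
    "ribosome",
    "golgi_apparatus",
    "mitochondria",
    "lysosome",
    "centrosome",
)


def default_aois(radius: float = 0.25, distance: float = 2.0) -> list[AOIDefinition]:
    """Sphere AOIs on a ring in front of the viewer (angular spacing 15 deg)."""
    aois = []
    n = len(ORGANELLES)
    for i, name in enumerate(ORGANELLES):
        ang = np.radians((i - (n - 1) / 2) * 15.0)
        center = (distance * np.sin(ang), 0.0, distance * np.cos(ang))
        aois.append(AOIDefinition(aoi_id=name, shape="sphere", center=center, size=radius))
    return aois


@dataclass(frozen=True)
class StateProfile:
    """Generative profile for one induced cognitive state.

    Event-duration supports sit safely inside the I-VT validity windows so
    that planted events survive detection.  ``metric_targets`` and
    ``scale_targets`` map names to (mean, sd) of the per-session aggregate.
    """

    state_label: int
    name: str
    fix_dur_range: tuple[float, float] = (0.150, 0.400)  # s
    sac_dur_range: tuple[float, float] = (0.042, 0.066)  # s
    fixation_jitter_deg: float = 0.05  # per-sample angular noise within fixations
    metric_targets: dict[str, tuple[float, float]] = field(default_factory=dict)
    scale_targets: dict[str, tuple[float, float]] = field(default_factory=dict)


def default_profiles() -> dict[int, StateProfile]:
    """The three study states parameterized by the published descriptives."""
    out = {}
    for label, name in STATE_NAMES.items():
        out[label] = StateProfile(
            state_label=label,
            name=name,
            metric_targets={m: ref.METRIC_STATS[m][label] for m in ref.METRIC_NAMES},
            scale_targets={s: ref.QUESTIONNAIRE_STATS[s][label] for s in ref.SCALE_NAMES},
        )
    return out


@dataclass(frozen=True)
class SimulationSpec:
    """Study-scale simulation layout.

    Defaults reproduce the study bookkeeping: 26 participants x 3 states,
    100 metric time steps per session (7800 labelled points, 2600 per
    class), gaze sampled at 120 Hz.  ``random_effect_scale`` multiplies the
    smallest per-state SD of each measure to give the shared
    per-participant effect SD (within-subject correlation).
    """

    n_participants: int = 26
    series_length: int = 100
    sample_rate: float = 120.0
    metric_grid_hz: float = 10.0
    seed: int = 0
    random_effect_scale: float = 0.5
    state_effects: bool = True  # False: all states share the overload profile means

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise SimulationConfigError("need at least 2 participants")
        if self.series_length < 2:
            raise SimulationConfigError("series_length must be >= 2")
        if self.sample_rate <= 0 or self.metric_grid_hz <= 0:
            raise SimulationConfigError("rates must be positive")


@dataclass
class GroundTruth:
    """Planted events of one simulated gaze stream."""

    events: list[tuple[str, float, float]]  # (kind, t_start, t_end)

    def counts(self) -> dict[str, int]:
        c = {FIXATION: 0, SACCADE: 0}
        for kind, _, _ in self.events:
            c[kind] += 1
        return c


@dataclass
class SessionRecord:
    """One participant-state session: metric series plus questionnaire scores."""

    participant_id: str
    state_label: int
    metrics: pd.DataFrame  # columns: t_s + the four metric channels
    questionnaire: dict[str, float] = field(default_factory=dict)

    def aggregates(self) -> dict[str, float]:
        """Final cumulative value of each metric (the per-session aggregate)."""
        last = self.metrics.iloc[-1]
        return {m: float(last[m]) for m in ref.METRIC_NAMES}


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _slerp(a: np.ndarray, b: np.ndarray, frac: float) -> np.ndarray:
    """Spherical interpolation between unit vectors."""
    dot = np.clip(np.dot(a, b), -1.0, 1.0)
    ang = np.arccos(dot)
    if ang < 1e-9:
        return a
    return (np.sin((1 - frac) * ang) * a + np.sin(frac * ang) * b) / np.sin(ang)


def _jitter(direction: np.ndarray, max_deg: float, rng: np.random.Generator) -> np.ndarray:
    if max_deg <= 0:
        return direction
    # random rotation away from `direction` by an angle <= max_deg
    perp = np.cross(direction, rng.normal(size=3))
    nrm = np.linalg.norm(perp)
    if nrm < 1e-12:
        return direction
    perp /= nrm
    ang = np.radians(rng.uniform(0, max_deg))
    v = np.cos(ang) * direction + np.sin(ang) * perp
    return v / np.linalg.norm(v)


def simulate_gaze_stream(
    profile: StateProfile,
    duration_s: float = 10.0,
    sample_rate: float = 120.0,
    seed: int | np.random.Generator = 0,
    aois: list[AOIDefinition] | None = None,
    noise: bool = True,
) -> tuple[GazeStream, GroundTruth]:
    """Simulate a gaze stream of alternating planted fixations and saccades.

    Fixations dwell on AOI centers with angular jitter far below the 30
    deg/s fixation gate; saccades rotate to the next AOI at constant
    angular velocity above the 60 deg/s saccade gate.  With ``noise=False``
    fixations are perfectly still.  Returns the stream and the planted
    ground truth (event kind and boundaries in seconds).
    """
    if duration_s <= 0:
        raise SimulationConfigError("duration_s must be positive")
    if sample_rate <= 0:
        raise SimulationConfigError("sample_rate must be positive")
    rng = _rng(seed)
    aois = aois if aois is not None else default_aois()
    centers = np.array([a.center for a in aois], dtype=float)
    targets = centers / np.linalg.norm(centers, axis=1)[:, None]

    dt = 1.0 / sample_rate
    n_total = int(round(duration_s * sample_rate)) + 1
    jit = profile.fixation_jitter_deg if noise else 0.0

    cur = int(rng.integers(len(targets)))
    dirs: list[np.ndarray] = [targets[cur]]
    truth: list[tuple[str, float, float]] = []
    kind = FIXATION
    while len(dirs) < n_total:
        i0 = len(dirs) - 1  # event starts at the last emitted sample
        if kind == FIXATION:
            n_pairs = int(round(rng.uniform(*profile.fix_dur_range) * sample_rate))
            for _ in range(n_pairs):
                dirs.append(_jitter(targets[cur], jit, rng))
        else:
            # rotate to a different AOI; ring spacing guarantees >= 15 deg,
            # so velocity = angle / duration clears the 60 deg/s gate
            nxt = int(rng.integers(len(targets) - 1))
            nxt = nxt if nxt < cur else nxt + 1
            n_pairs = int(round(rng.uniform(*profile.sac_dur_range) * sample_rate))
            n_pairs = max(n_pairs, 4)
            start = dirs[-1]
            for j in range(1, n_pairs + 1):
                dirs.append(_slerp(start, targets[nxt], j / n_pairs))
            cur = nxt
        i1 = len(dirs) - 1
        if i1 >= n_total:
            break  # incomplete tail event is not part of the ground truth
        truth.append((kind, i0 * dt, i1 * dt))
        kind = SACCADE if kind == FIXATION else FIXATION

    # trim the incomplete tail so the stream contains exactly the planted events
    last = int(round(truth[-1][2] / dt)) if truth else len(dirs) - 1
    dirs_arr = np.array(dirs[: last + 1])
    t = np.arange(len(dirs_arr)) * dt
    return GazeStream(t=t, dirs=dirs_arr), GroundTruth(events=truth)


def _random_effect_sd(targets_by_state: dict[int, tuple[float, float]], scale: float) -> float:
    return scale * min(sd for _, sd in targets_by_state.values())


def _draw_aggregate(
    mean: float, sd: float, re_sd: float, u: float, rng: np.random.Generator
) -> float:
    resid = float(np.sqrt(max(sd * sd - re_sd * re_sd, 1e-12)))
    return mean + u + rng.normal(0.0, resid)


def _metric_path(
    length: int,
    grid_hz: float,
    count: int,
    total_duration: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Monotone cumulative (duration, count) paths reaching the aggregates.

    ``count`` event completions are placed uniformly over the step grid;
    each completion adds one count and an equal share of the total
    duration.  Returns (t, duration_path, count_path).
    """
    t = np.arange(length) / grid_hz
    counts = np.zeros(length)
    if count > 0:
        steps = rng.integers(0, length, size=count)
        counts = np.cumsum(np.bincount(steps, minlength=length))
    dur = counts * (total_duration / count if count > 0 else 0.0)
    return t, dur, counts.astype(float)


def simulate_metric_dataset(
    spec: SimulationSpec,
    profiles: dict[int, StateProfile] | None = None,
    rng: np.random.Generator | None = None,
) -> list[SessionRecord]:
    """Per-participant, per-state cumulative metric time series.

    Session aggregates are normal draws around the profile targets with an
    additive per-participant effect shared across states (SD =
    ``random_effect_scale`` x the smallest per-state SD of the measure);
    values are clipped at zero and counts rounded to integers.  Each series
    has ``series_length`` steps, so the default spec yields 26 x 3 = 78
    sessions and 7800 labelled time steps, 2600 per class.
    """
    profiles = profiles or default_profiles()
    if set(profiles) != {0, 1, 2}:
        raise SimulationConfigError("need one profile per state 0/1/2")
    rng = rng if rng is not None else _substreams(spec.seed, 3)[1]

    re_sds = {
        m: _random_effect_sd(
            {s: profiles[s].metric_targets[m] for s in profiles}, spec.random_effect_scale
        )
        for m in ref.METRIC_NAMES
    }
    records: list[SessionRecord] = []
    for p in range(spec.n_participants):
        pid = f"P{p + 1:02d}"
        u = {m: rng.normal(0.0, re_sds[m]) for m in ref.METRIC_NAMES}
        for state in sorted(profiles):
            prof = profiles[state] if spec.state_effects else profiles[0]
            agg = {}
            for m in ref.METRIC_NAMES:
                mean, sd = prof.metric_targets[m]
                agg[m] = max(0.0, _draw_aggregate(mean, sd, re_sds[m], u[m], rng))
            n_fix = int(round(agg["fixation_count"]))
            n_sac = int(round(agg["saccade_count"]))
            t, fd, fc = _metric_path(
                spec.series_length, spec.metric_grid_hz, n_fix, agg["fixation_duration"], rng
            )
            _, sd_path, sc = _metric_path(
                spec.series_length, spec.metric_grid_hz, n_sac, agg["saccade_duration"], rng
            )
            metrics = pd.DataFrame(
                {
                    "t_s": t,
                    "fixation_duration": fd,
                    "fixation_count": fc,
                    "saccade_duration": sd_path,
                    "saccade_count": sc,
                }
            )
            records.append(
                SessionRecord(participant_id=pid, state_label=state, metrics=metrics)
            )
    return records


def simulate_questionnaires(
    spec: SimulationSpec,
    profiles: dict[int, StateProfile] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-session scale scores drawn around the profile targets.

    Same random-effect structure as the metric aggregates; draws are
    truncated (clipped) to the scale bounds.  Returns a DataFrame with
    columns ``participant_id, state`` plus one column per scale.
    """
    profiles = profiles or default_profiles()
    rng = rng if rng is not None else _substreams(spec.seed, 3)[2]
    re_sds = {
        s: _random_effect_sd(
            {st: profiles[st].scale_targets[s] for st in profiles}, spec.random_effect_scale
        )
        for s in ref.SCALE_NAMES
    }
    rows = []
    for p in range(spec.n_participants):
        pid = f"P{p + 1:02d}"
        u = {s: rng.normal(0.0, re_sds[s]) for s in ref.SCALE_NAMES}
        for state in sorted(profiles):
            prof = profiles[state] if spec.state_effects else profiles[0]
            row = {"participant_id": pid, "state": state}
            for s in ref.SCALE_NAMES:
                mean, sdev = prof.scale_targets[s]
                lo, hi = ref.SCALE_BOUNDS[s]
                val = _draw_aggregate(mean, sdev, re_sds[s], u[s], rng) if sdev > 0 else mean
                row[s] = float(np.clip(val, lo, hi))
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_dataset(
    spec: SimulationSpec, profiles: dict[int, StateProfile] | None = None
) -> list[SessionRecord]:
    """Full study-shaped dataset: metric series with questionnaire scores."""
    profiles = profiles or default_profiles()
    _, rng_metrics, rng_quest = _substreams(spec.seed, 3)
    records = simulate_metric_dataset(spec, profiles, rng_metrics)
    quest = simulate_questionnaires(spec, profiles, rng_quest)
    by_key = {
        (r.participant_id, r.state): {s: getattr(r, s) for s in ref.SCALE_NAMES}
        for r in quest.itertuples(index=False)
    }
    for rec in records:
        rec.questionnaire = by_key[(rec.participant_id, rec.state_label)]
    return records


def sessions_to_long(records: list[SessionRecord]) -> pd.DataFrame:
    """Long table (participant_id, state, measure, value) of session
    aggregates and questionnaire scores, the input to the statistical
    battery."""
    rows = []
    for rec in records:
        for m, v in rec.aggregates().items():
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "state": rec.state_label,
                    "measure": m,
                    "value": v,
                }
            )
        for s, v in rec.questionnaire.items():
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "state": rec.state_label,
                    "measure": s,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


def null_profiles() -> dict[int, StateProfile]:
    """Profiles with no state effect (all states share the overload targets);
    used for type-I-error calibration of the RM-ANOVA."""
    base = default_profiles()
    return {s: replace(base[s], metric_targets=dict(base[0].metric_targets),
                       scale_targets=dict(base[0].scale_targets)) for s in base}
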