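"""End-to-end orchestration: simulate -> detect -> metrics -> stats -> classify.

Each stage reads the files the previous stage wrote (CSV/JSON only), so the
pipeline also exercises every external interface.  A run directory gains a
``manifest.json`` recording the configuration, the seed, and SHA-256
checksums of every output file; deterministic stages reproduce identical
checksums for identical configurations.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from gazestate import synthetic
from gazestate.aoi_metrics import (
    accumulate_metrics,
    attribute_events,
    load_aois,
    save_aois,
    write_metrics_csv,
)
from gazestate.gaze_events import GazeStream, ThresholdConfig, detect_events, write_events_csv
from gazestate.state_classifier import Hyperparams, build_dataset, run_loso, summarize_runs
from gazestate.stats_analysis import run_battery
from gazestate.synthetic import SessionRecord, SimulationSpec

log = logging.getLogger("gazestate")

ALL_STAGES = ("simulate", "detect", "metrics", "stats", "classify")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "runs/default"
    seed: int = 7
    stages: tuple[str, ...] = ALL_STAGES
    spec: SimulationSpec = field(default_factory=SimulationSpec)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    classifier: str = "lstm"
    gaze_duration_s: float = 10.0
    # number of simulated raw gaze streams (one per participant-state up to
    # this cap); metric series are always generated for every session
    max_gaze_streams: int = 6
    aoi_file: str | None = None
    log_level: str = "INFO"


def validate_config(raw: dict) -> RunConfig:
    """Build a RunConfig from a plain dict, aggregating all errors."""
    errors: list[str] = []
    known = {f for f in RunConfig.__dataclass_fields__}
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key {key!r}")
    kwargs = dict(raw)
    for name, cls in (("spec", SimulationSpec), ("thresholds", ThresholdConfig),
                      ("hyperparams", Hyperparams)):
        if name in kwargs and isinstance(kwargs[name], dict):
            try:
                kwargs[name] = cls(**kwargs[name])
            except (TypeError, ValueError) as exc:
                errors.append(f"{name}: {exc}")
                kwargs.pop(name)
    kwargs = {k: v for k, v in kwargs.items() if k in known}
    try:
        cfg = RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    if cfg.hyperparams.window_length > cfg.spec.series_length:
        errors.append(
            f"window length {cfg.hyperparams.window_length} exceeds series "
            f"length {cfg.spec.series_length}"
        )
    for st in cfg.stages:
        if st not in ALL_STAGES:
            errors.append(f"unknown stage {st!r}")
    if "simulate" not in cfg.stages:
        if cfg.aoi_file is not None and not Path(cfg.aoi_file).exists():
            errors.append(f"AOI file not found: {cfg.aoi_file}")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_sessions(out: Path, spec: SimulationSpec) -> list[SessionRecord]:
    """Reload simulated session records from the stage output files."""
    quest = pd.read_csv(out / "questionnaires.csv")
    records = []
    for _, row in quest.iterrows():
        pid, state = row["participant_id"], int(row["state"])
        metrics = pd.read_csv(out / f"metrics_{pid}_{state}.csv", comment="#")
        q = {k: float(row[k]) for k in quest.columns if k not in ("participant_id", "state")}
        records.append(
            SessionRecord(participant_id=pid, state_label=state, metrics=metrics,
                          questionnaire=q)
        )
    return records


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the selected stages in dependency order; returns the run dir.

    Stage failures abort with a stage-named error; outputs written before
    the failure are retained for inspection.
    """
    logging.basicConfig(level=cfg.log_level, format="%(levelname)s %(name)s: %(message)s")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "config": {
            "spec": asdict(cfg.spec),
            "thresholds": asdict(cfg.thresholds),
            "hyperparams": asdict(cfg.hyperparams),
            "classifier": cfg.classifier,
        },
        "outputs": {},
        "timings_s": {},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()

    profiles = synthetic.default_profiles()
    aois = load_aois(cfg.aoi_file) if cfg.aoi_file else synthetic.default_aois()
    # single-seed policy: the run seed overrides stage-level seeds
    spec = replace(cfg.spec, seed=cfg.seed)
    cfg = replace(cfg, spec=spec, hyperparams=replace(cfg.hyperparams, seed=cfg.seed))
    records: list[SessionRecord] | None = None

    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.time()
        log.info("stage %s starting", stage)
        try:
            if stage == "simulate":
                records = synthetic.simulate_dataset(spec, profiles)
                for rec in records:
                    df = rec.metrics.copy()
                    df.to_csv(
                        out / f"metrics_{rec.participant_id}_{rec.state_label}.csv",
                        index=False,
                        float_format="%.6f",
                    )
                rows = []
                for rec in records:
                    rows.append(
                        {"participant_id": rec.participant_id, "state": rec.state_label,
                         **rec.questionnaire}
                    )
                pd.DataFrame(rows).to_csv(out / "questionnaires.csv", index=False,
                                          float_format="%.6f")
                save_aois(aois, out / "aoi.json")
                gaze_rngs = np.random.SeedSequence(cfg.seed).spawn(1)[0].spawn(
                    cfg.max_gaze_streams
                )
                truth = {}
                sessions = [(r.participant_id, r.state_label) for r in records]
                for (pid, state), ss in zip(sessions[: cfg.max_gaze_streams], gaze_rngs):
                    stream, gt = synthetic.simulate_gaze_stream(
                        profiles[state],
                        duration_s=cfg.gaze_duration_s,
                        sample_rate=spec.sample_rate,
                        seed=np.random.default_rng(ss),
                        aois=aois,
                    )
                    stream.to_csv(out / f"gaze_{pid}_{state}.csv")
                    truth[f"{pid}_{state}"] = [
                        {"kind": k, "t_start": a, "t_end": b} for k, a, b in gt.events
                    ]
                with open(out / "ground_truth.json", "w") as fh:
                    json.dump(truth, fh, indent=2)

            elif stage == "detect":
                for gaze_csv in sorted(out.glob("gaze_*.csv")):
                    stream = GazeStream.from_csv(gaze_csv)
                    events = detect_events(stream, cfg.thresholds)
                    write_events_csv(events, out / gaze_csv.name.replace("gaze_", "events_"))

            elif stage == "metrics":
                for gaze_csv in sorted(out.glob("gaze_*.csv")):
                    stream = GazeStream.from_csv(gaze_csv)
                    events = detect_events(stream, cfg.thresholds)
                    attribute_events(events, stream, aois)
                    series = accumulate_metrics(
                        events, aois, t_end=float(stream.t[-1]), grid_rate=spec.metric_grid_hz
                    )
                    write_metrics_csv(
                        series, out / gaze_csv.name.replace("gaze_", "aoi_metrics_")
                    )

            elif stage == "stats":
                if records is None:
                    records = _read_sessions(out, spec)
                long = synthetic.sessions_to_long(records)
                long.to_csv(out / "sessions_long.csv", index=False, float_format="%.6f")
                run_battery(long, out_dir=out / "stats")

            elif stage == "classify":
                if records is None:
                    records = _read_sessions(out, spec)
                hp = cfg.hyperparams
                X, y, groups = build_dataset(
                    records, T=hp.window_length, include_time=hp.include_time
                )
                reports = run_loso(X, y, groups, hp, model=cfg.classifier)
                res = summarize_runs(reports)
                res["per_subject"].to_csv(out / "per_subject_accuracy.csv", index=False)
                res["classwise"].to_csv(out / "classwise.csv", index=False)
                pd.DataFrame(
                    [
                        {"participant_id": r.participant_id, "accuracy": r.accuracy,
                         "f1_macro": r.f1_macro, "recall_macro": r.recall_macro,
                         "auc_macro": r.auc_macro, "loss": r.loss}
                        for r in reports
                    ]
                ).to_csv(out / "folds.csv", index=False)
                with open(out / "summary.json", "w") as fh:
                    json.dump(res["summary"], fh, indent=2)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["timings_s"][stage] = round(time.time() - t0, 3)
        log.info("stage %s done in %.1fs", stage, manifest["timings_s"][stage])

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
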