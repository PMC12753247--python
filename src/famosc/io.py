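"""Session-bundle readers/writers.

A bundle is a directory with a versioned ``manifest.json`` naming the
payload files:

* recording — ``lfp.bin`` (little-endian float32, channel-major) +
  ``lfp.json`` sidecar, ``spikes.csv`` (unit_id, spike_time_s,
  trough_to_peak_ms, depth_um), ``events.csv`` (trial_index, onset_s,
  direction_deg, condition);
* behavior — ``trials.csv`` (session_day, trial_index, trial_type, touched,
  latency_s, intertrial_touches_after);
* trajectory — ``track.csv`` (frame, x, y) + ``geom.json``.

All invariants are checked at load time (pydantic for the JSON schemas,
container validation for the arrays), so analysis code never sees an
invariant-violating object. Generated and ingested bundles are
indistinguishable to the pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from pydantic import ValidationError as PydanticValidationError

from .behavior import ChamberGeometry
from .types import (BehaviorSession, BehaviorTrial, RecordingSession,
                    SpikeTrain, TrajectoryRecord, TrialLayout,
                    ValidationError)

SCHEMA_VERSION = 1


class LfpSidecar(BaseModel):
    sampling_rate_hz: float = Field(gt=0)
    n_channels: int = Field(ge=1)
    channel_depth_um: list[float]
    units: str = "uV"


class LayoutModel(BaseModel):
    epoch_length: float
    baseline_window: tuple[float, float]
    stimulus_window: tuple[float, float]
    n_trials: int
    sampling_rate_lfp: float
    directions: list[float] = []


class Manifest(BaseModel):
    schema_version: int
    kind: str  # {recording, behavior, trajectory}
    components: dict[str, str]
    layout: LayoutModel | None = None
    animal_id: str = "synthetic"
    condition: str = "post"
    group: str = ""


def _layout_to_model(layout: TrialLayout) -> LayoutModel:
    return LayoutModel(epoch_length=layout.epoch_length,
                       baseline_window=layout.baseline_window,
                       stimulus_window=layout.stimulus_window,
                       n_trials=layout.n_trials,
                       sampling_rate_lfp=layout.sampling_rate_lfp,
                       directions=list(layout.directions))


def _model_to_layout(m: LayoutModel) -> TrialLayout:
    return TrialLayout(epoch_length=m.epoch_length,
                       baseline_window=tuple(m.baseline_window),
                       stimulus_window=tuple(m.stimulus_window),
                       n_trials=m.n_trials,
                       sampling_rate_lfp=m.sampling_rate_lfp,
                       directions=tuple(m.directions))


def write_recording_bundle(path: str | Path,
                           session: RecordingSession) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    components: dict[str, str] = {"events": "events.csv"}
    pd.DataFrame({
        "trial_index": np.arange(session.n_trials),
        "onset_s": session.trial_onsets,
        "direction_deg": session.trial_directions,
        "condition": session.condition,
    }).to_csv(path / "events.csv", index=False)
    if session.lfp is not None:
        session.lfp.astype("<f4").tofile(path / "lfp.bin")
        sidecar = LfpSidecar(
            sampling_rate_hz=float(session.lfp_rate),
            n_channels=session.lfp.shape[0],
            channel_depth_um=(
                list(map(float, session.channel_depths_um))
                if session.channel_depths_um is not None
                else [0.0] * session.lfp.shape[0]))
        (path / "lfp.json").write_text(sidecar.model_dump_json(indent=1))
        components["lfp"] = "lfp.bin"
        components["lfp_sidecar"] = "lfp.json"
    if session.spike_trains:
        rows = []
        for tr in session.spike_trains:
            rows.append(pd.DataFrame({
                "unit_id": tr.unit_id, "spike_time_s": tr.times,
                "trough_to_peak_ms": tr.trough_to_peak_ms,
                "depth_um": tr.depth_um}))
        pd.concat(rows, ignore_index=True).to_csv(
            path / "spikes.csv", index=False)
        components["spikes"] = "spikes.csv"
    manifest = Manifest(schema_version=SCHEMA_VERSION, kind="recording",
                        components=components,
                        layout=_layout_to_model(session.layout),
                        animal_id=session.animal_id,
                        condition=session.condition, group=session.group)
    (path / "manifest.json").write_text(manifest.model_dump_json(indent=1))
    return path


def write_behavior_bundle(path: str | Path, sessions: list[BehaviorSession],
                          group: str = "") -> Path:
    """The per-session inter-trial touch total is recorded on the final
    trial row of each day (column ``intertrial_touches_after``)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sessions:
        for i, t in enumerate(s.trials):
            rows.append({
                "session_day": s.session_day, "trial_index": i,
                "trial_type": t.trial_type, "touched": int(t.touched),
                "latency_s": (t.latency_s if t.latency_s is not None
                              else np.nan),
                "intertrial_touches_after":
                    s.intertrial_touches if i == len(s.trials) - 1 else 0})
    pd.DataFrame(rows).to_csv(path / "trials.csv", index=False)
    manifest = Manifest(schema_version=SCHEMA_VERSION, kind="behavior",
                        components={"trials": "trials.csv"}, group=group)
    (path / "manifest.json").write_text(manifest.model_dump_json(indent=1))
    return path


def write_trajectory_bundle(path: str | Path, track: TrajectoryRecord,
                            geom: ChamberGeometry, group: str = "") -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "frame": np.arange(track.positions.shape[0]),
        "x": track.positions[:, 0], "y": track.positions[:, 1],
    }).to_csv(path / "track.csv", index=False)
    geom.to_json(path / "geom.json")
    manifest = Manifest(schema_version=SCHEMA_VERSION, kind="trajectory",
                        components={"track": "track.csv",
                                    "geometry": "geom.json",
                                    "fps": str(track.fps)},
                        group=group)
    (path / "manifest.json").write_text(manifest.model_dump_json(indent=1))
    return path


def _load_manifest(path: Path) -> Manifest:
    mf = path / "manifest.json"
    if not mf.exists():
        raise ValidationError(f"{path}: no manifest.json")
    try:
        manifest = Manifest.model_validate_json(mf.read_text())
    except PydanticValidationError as exc:
        msgs = "; ".join(f"{'.'.join(map(str, e['loc']))}: {e['msg']}"
                         for e in exc.errors())
        raise ValidationError(f"{mf}: {msgs}") from exc
    if manifest.schema_version != SCHEMA_VERSION:
        raise ValidationError(
            f"{mf}: unknown schema version {manifest.schema_version} "
            f"(expected {SCHEMA_VERSION})")
    return manifest


def _read_recording(path: Path, manifest: Manifest) -> RecordingSession:
    if manifest.layout is None:
        raise ValidationError(f"{path}: recording bundle without a layout")
    layout = _model_to_layout(manifest.layout)
    events = pd.read_csv(path / manifest.components["events"], float_precision="round_trip")
    lfp = lfp_rate = depths = None
    if "lfp" in manifest.components:
        try:
            sidecar = LfpSidecar.model_validate_json(
                (path / manifest.components["lfp_sidecar"]).read_text())
        except PydanticValidationError as exc:
            msgs = "; ".join(f"{'.'.join(map(str, e['loc']))}: {e['msg']}"
                             for e in exc.errors())
            raise ValidationError(f"{path}/lfp.json: {msgs}") from exc
        flat = np.fromfile(path / manifest.components["lfp"], dtype="<f4")
        if flat.size % sidecar.n_channels:
            raise ValidationError(
                f"{path}: lfp.bin size not divisible by n_channels")
        lfp = flat.reshape(sidecar.n_channels, -1)
        lfp_rate = sidecar.sampling_rate_hz
        depths = np.asarray(sidecar.channel_depth_um)
    trains: list[SpikeTrain] = []
    if "spikes" in manifest.components:
        sp = pd.read_csv(path / manifest.components["spikes"], float_precision="round_trip")
        for uid, grp in sp.groupby("unit_id", sort=True):
            trains.append(SpikeTrain(
                unit_id=str(uid), times=grp["spike_time_s"].to_numpy(),
                trough_to_peak_ms=float(grp["trough_to_peak_ms"].iloc[0]),
                depth_um=float(grp["depth_um"].iloc[0])))
    return RecordingSession(
        layout=layout, trial_onsets=events["onset_s"].to_numpy(),
        trial_directions=events["direction_deg"].to_numpy(),
        lfp=lfp, lfp_rate=lfp_rate, channel_depths_um=depths,
        spike_trains=trains, animal_id=manifest.animal_id,
        condition=manifest.condition, group=manifest.group)


def _read_behavior(path: Path, manifest: Manifest) -> list[BehaviorSession]:
    df = pd.read_csv(path / manifest.components["trials"], float_precision="round_trip")
    sessions = []
    for day, grp in df.groupby("session_day", sort=True):
        trials = []
        for _, row in grp.sort_values("trial_index").iterrows():
            touched = bool(row["touched"])
            lat = row["latency_s"]
            lat = float(lat) if touched and pd.notna(lat) else None
            trials.append(BehaviorTrial(str(row["trial_type"]), touched, lat))
        sessions.append(BehaviorSession(
            session_day=int(day), trials=trials,
            intertrial_touches=int(grp["intertrial_touches_after"].sum())))
    return sessions


def _read_trajectory(path: Path, manifest: Manifest
                     ) -> tuple[TrajectoryRecord, ChamberGeometry]:
    df = pd.read_csv(path / manifest.components["track"], float_precision="round_trip")
    geom = ChamberGeometry.from_json(path / manifest.components["geometry"])
    track = TrajectoryRecord(
        fps=float(manifest.components["fps"]),
        positions=df[["x", "y"]].to_numpy())
    return track, geom


def read_session_bundle(path: str | Path):
    """Load a bundle; returns a RecordingSession, a list of BehaviorSession,
    or a (TrajectoryRecord, ChamberGeometry) pair depending on its kind."""
    path = Path(path)
    manifest = _load_manifest(path)
    missing = [f for f in manifest.components.values()
               if f.endswith((".csv", ".bin", ".json"))
               and not (path / f).exists()]
    if missing:
        raise ValidationError(f"{path}: missing payload files {missing}")
    if manifest.kind == "recording":
        return _read_recording(path, manifest)
    if manifest.kind == "behavior":
        return _read_behavior(path, manifest)
    if manifest.kind == "trajectory":
        return _read_trajectory(path, manifest)
    raise ValidationError(f"{path}: unknown bundle kind {manifest.kind!r}")
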