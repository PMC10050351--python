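"""Session and model persistence.

A session is a directory holding one raw little-endian float32 array per
trial (channels x samples, C order, `trial_NNN.f32`) plus `session.json`
with channel names, sample rate, per-trial event tables (data-time
onsets), ground-truth characters, the subject profile and seed. The
reader reconstructs the same `SessionSet` bit-exactly, epochs re-cut
from the continuous per-trial records at the stored onsets.

Trained models (P300 ensemble, TRCA, fusion controller) are serialized
with joblib.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import joblib
import numpy as np

from .paradigm import ALL_LINES, LineID, TrialSchedule
from .preprocess import segment
from .synth import (
    CHANNEL_NAMES,
    N_CHANNELS,
    SAMPLE_RATE_HZ,
    SessionSet,
    SubjectProfile,
    TrialRecord,
)


def write_session(session: SessionSet, path) -> Path:
    """Persist a session as raw float32 trial files + JSON metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "sample_rate": SAMPLE_RATE_HZ,
        "channel_names": list(CHANNEL_NAMES),
        "kind": session.kind,
        "profile": asdict(session.profile) if session.profile else None,
        "trials": [],
    }
    for i, trial in enumerate(session.trials):
        data, events = trial.to_continuous()
        fname = f"trial_{i:03d}.f32"
        data.astype("<f4").tofile(path / fname)
        meta["trials"].append({
            "file": fname,
            "n_samples": int(data.shape[1]),
            "character": trial.character,
            "trial_id": trial.trial_id,
            "epoch_ids": [ep.epoch_id for ep in trial.epochs],
            "schedule_flat": [l.flat_index for l in trial.schedule.flashes],
            "events": events,
        })
    (path / "session.json").write_text(json.dumps(meta, indent=1))
    return path


def read_session(path) -> SessionSet:
    """Load a session directory written by `write_session`."""
    path = Path(path)
    meta = json.loads((path / "session.json").read_text())
    trials = []
    for tmeta in meta["trials"]:
        raw = np.fromfile(path / tmeta["file"], dtype="<f4")
        record = raw.reshape(N_CHANNELS, tmeta["n_samples"])
        epochs = segment(record, tmeta["events"], fs=meta["sample_rate"])
        for ep, eid in zip(epochs, tmeta["epoch_ids"]):
            ep.trial_id = tmeta["trial_id"]
            ep.epoch_id = eid
        schedule = TrialSchedule(
            flashes=[LineID.from_flat(f) for f in tmeta["schedule_flat"]])
        trials.append(TrialRecord(epochs=epochs, character=tmeta["character"],
                                  schedule=schedule, trial_id=tmeta["trial_id"]))
    profile = SubjectProfile(**meta["profile"]) if meta["profile"] else None
    return SessionSet(trials=trials, kind=meta["kind"], profile=profile)


def save_model(model, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, path)
    return path


def load_model(path):
    return joblib.load(path)
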