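"""EEG preprocessing: 60 Hz notch, linear detrend, epoching, channel split.

The continuous record is notch-filtered (zero-phase second-order IIR,
Q = 30) to remove power-line interference, linearly detrended per channel,
cut into 0-800 ms flash-locked epochs, and split into the two decoder
views: 8 fronto-parietal channels for P300 and 9 occipital channels for
SSVEP (four channels are shared). Sample indexing is 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import signal

from .paradigm import LineID
from .synth import (
    CHANNEL_NAMES,
    EPOCH_SAMPLES,
    FlashEpoch,
    SAMPLE_RATE_HZ,
    SessionSet,
    TrialRecord,
)

P300_CHANNELS: Sequence[str] = ("Fz", "Cz", "P3", "P4", "PO7", "PO8", "Pz", "Oz")
SSVEP_CHANNELS: Sequence[str] = ("PO7", "PO8", "Pz", "Oz", "O1", "O2", "PO3", "PO4", "POz")


@dataclass(frozen=True)
class ChannelSplit:
    p300_channels: Sequence[str] = P300_CHANNELS
    ssvep_channels: Sequence[str] = SSVEP_CHANNELS


def notch_60(data: np.ndarray, fs: float = SAMPLE_RATE_HZ) -> np.ndarray:
    """Zero-phase 60 Hz notch (IIR, Q=30, forward-backward) along last axis."""
    if fs != SAMPLE_RATE_HZ:
        raise ValueError(f"expected sample rate {SAMPLE_RATE_HZ}, got {fs}")
    data = np.asarray(data, dtype=float)
    b, a = signal.iirnotch(60.0, Q=30.0, fs=fs)
    # the high-Q notch has a long impulse response; pad well past it
    padlen = min(data.shape[-1] - 1, 250)
    return signal.filtfilt(b, a, data, axis=-1, padlen=padlen)


def detrend(data: np.ndarray) -> np.ndarray:
    """Remove the per-channel least-squares linear trend (baseline correction)."""
    return signal.detrend(np.asarray(data, dtype=float), axis=-1, type="linear")


def segment(record: np.ndarray, events: List[dict],
            fs: float = SAMPLE_RATE_HZ) -> List[FlashEpoch]:
    """Cut a continuous (channels, samples) record into 0-800 ms flash epochs.

    Each event yields samples [round(onset*fs), round(onset*fs)+200),
    tagged with the event's line identity and target flag.
    """
    record = np.asarray(record)
    out: List[FlashEpoch] = []
    for ev in events:
        start = int(round(ev["onset_s"] * fs))
        stop = start + EPOCH_SAMPLES
        if start < 0 or stop > record.shape[-1]:
            raise ValueError(f"epoch [{start}, {stop}) extends past the record")
        line = LineID.from_flat(ev["flat_index"])
        out.append(FlashEpoch(
            data=record[:, start:stop],
            line=line,
            frequency=ev["frequency_hz"],
            is_target=bool(ev["is_target"]),
            trial_id=ev.get("trial_id", 0),
            epoch_id=ev.get("epoch_id", 0),
        ))
    return out


def _indices(channels: Sequence[str], montage: Sequence[str]) -> List[int]:
    idx = []
    for name in channels:
        if name not in montage:
            raise KeyError(f"channel {name!r} missing from montage")
        idx.append(montage.index(name))
    return idx


def split_channels(epoch: FlashEpoch, split: ChannelSplit = ChannelSplit(),
                   montage: Sequence[str] = CHANNEL_NAMES) -> Tuple[np.ndarray, np.ndarray]:
    """(8 x 200 P300 view, 9 x 200 SSVEP view), rows in ChannelSplit order."""
    p_idx = _indices(split.p300_channels, montage)
    s_idx = _indices(split.ssvep_channels, montage)
    return epoch.data[p_idx, :], epoch.data[s_idx, :]


def preprocess_trial(trial: TrialRecord) -> List[FlashEpoch]:
    """notch -> detrend -> segment on one trial's continuous record."""
    record, events = trial.to_continuous()
    for k, ev in enumerate(events):
        ev["trial_id"] = trial.trial_id
        ev["epoch_id"] = trial.epochs[k].epoch_id
    clean = detrend(notch_60(record))
    return segment(clean, events)


def preprocess_session(session: SessionSet) -> List[List[FlashEpoch]]:
    """Preprocessed epochs per trial, in session order."""
    return [preprocess_trial(t) for t in session.trials]
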