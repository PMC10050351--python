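"""Synthetic multichannel EEG sessions for the hybrid speller.

Generates flash-locked epochs with the statistical structure the decoders
assume: a P300 — a positive, roughly Gaussian deflection peaking ~300 ms
after a *target* flash, projected onto a fronto-parietal topography — and
a frequency-tagged SSVEP — sinusoids at the flashed line's frequency and
its harmonics, projected onto an occipital topography — superimposed on
1/f^alpha ("pink") background noise. Under the default gaze model only
the fixated (target) line evokes an SSVEP, so the two target flashes of a
trial carry both signals and the ten non-target flashes carry noise only.

A calibration session mirrors the speller's training protocol: 11 blocks
of 12 spelled characters, i.e. 132 trials and 1,584 flash epochs with a
1:5 target:non-target ratio. Copy-spelling sessions spell a given text,
one trial per character.

The generator emulates amplitude topographies, latency jitter, partial
phase locking and pink noise; it does not attempt biophysical forward
modeling, ocular/muscular artifacts, or electrode drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence

import numpy as np

from .paradigm import (
    ALL_LINES,
    CharacterGrid,
    LineID,
    TrialSchedule,
    line_frequency,
    make_trial_schedule,
    schedule_event_table,
)

SAMPLE_RATE_HZ = 250.0
EPOCH_SAMPLES = 200  # 0.8 s at 250 Hz
CHANNEL_NAMES: Sequence[str] = (
    "Fz", "Cz", "P3", "P4", "PO7", "PO8", "Pz", "Oz", "O1", "O2", "PO3", "PO4", "POz",
)
N_CHANNELS = len(CHANNEL_NAMES)

CALIBRATION_BLOCKS = 11
TRIALS_PER_BLOCK = 12


def _unit_topography(weights: dict) -> np.ndarray:
    """Fixed channel weight vector, montage order, normalized to unit peak.

    Peak normalization makes the profile amplitudes read as the evoked
    amplitude at the component's peak electrode (Cz/Pz for the P300, Oz
    for the SSVEP), which is how such amplitudes are quoted for real EEG.
    """
    v = np.array([weights.get(ch, 0.05) for ch in CHANNEL_NAMES], dtype=float)
    return v / v.max()


# P300 is fronto-parietal (peaks at Cz/Pz); SSVEP is occipital (peaks at Oz).
P300_TOPOGRAPHY = _unit_topography(
    {"Fz": 0.5, "Cz": 1.0, "P3": 0.6, "P4": 0.6, "Pz": 0.9, "PO7": 0.3, "PO8": 0.3, "Oz": 0.2}
)
SSVEP_TOPOGRAPHY = _unit_topography(
    {"Oz": 1.0, "O1": 0.8, "O2": 0.8, "POz": 0.9, "PO3": 0.7, "PO4": 0.7,
     "PO7": 0.5, "PO8": 0.5, "Pz": 0.4}
)


@dataclass
class RecordingConfig:
    sample_rate: float = SAMPLE_RATE_HZ
    channel_names: Sequence[str] = CHANNEL_NAMES


@dataclass
class SubjectProfile:
    """Signal-model parameters of one simulated subject.

    Amplitudes are in microvolts, times in seconds. Defaults keep
    single-flash P300 detection genuinely hard (5 uV bump against 8 uV
    pink noise) while leaving the frequency-tagged SSVEP decodable from
    trial-averaged templates, so that the hybrid decoder has headroom
    over either modality alone.
    """

    p300_amplitude: float = 5.0
    p300_latency: float = 0.30
    p300_width: float = 0.05
    latency_jitter_sd: float = 0.02
    ssvep_amplitude: float = 2.0
    n_harmonics: int = 3
    harmonic_decay: float = 0.5
    nontarget_ssvep_gain: float = 0.0  # gaze model: only the fixated line drives SSVEP
    phase_locking: float = 0.8  # fraction of SSVEP amplitude with trial-fixed phase
    noise_sd: float = 8.0
    noise_exponent: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.p300_amplitude < 0 or self.ssvep_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise_sd must be non-negative")
        if not 0.0 <= self.nontarget_ssvep_gain < 1.0:
            raise ValueError("nontarget_ssvep_gain must lie in [0, 1)")


@dataclass
class FlashEpoch:
    """One 0.8 s, 13-channel segment following a single line flash."""

    data: np.ndarray  # (13, 200), microvolts
    line: LineID
    frequency: float
    is_target: bool
    trial_id: int = 0
    epoch_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != (N_CHANNELS, EPOCH_SAMPLES):
            raise ValueError(f"epoch data must be {(N_CHANNELS, EPOCH_SAMPLES)}, got {self.data.shape}")
        if abs(self.frequency - line_frequency(self.line)) > 1e-9:
            raise ValueError("epoch frequency must match the paradigm assignment for its line")


@dataclass
class TrialRecord:
    """12 flash epochs (each line once) plus the spelled character."""

    epochs: List[FlashEpoch]
    character: str
    schedule: TrialSchedule
    trial_id: int = 0

    def to_continuous(self):
        """Concatenated (13, 2400) record + data-time event table.

        Inter-flash intervals and the cue carry no simulated data, so
        epoch k starts at data-time 0.8*k s.
        """
        data = np.concatenate([ep.data for ep in self.epochs], axis=1)
        events = [
            {
                "onset_s": k * EPOCH_SAMPLES / SAMPLE_RATE_HZ,
                "flat_index": ep.line.flat_index,
                "frequency_hz": ep.frequency,
                "is_target": bool(ep.is_target),
            }
            for k, ep in enumerate(self.epochs)
        ]
        return data, events


@dataclass
class SessionSet:
    trials: List[TrialRecord]
    kind: str  # "calibration" | "copy" | "free"
    config: RecordingConfig = field(default_factory=RecordingConfig)
    profile: Optional[SubjectProfile] = None

    @property
    def flash_count(self) -> int:
        return sum(len(t.epochs) for t in self.trials)

    def all_epochs(self) -> List[FlashEpoch]:
        return [ep for t in self.trials for ep in t.epochs]


def pink_noise(rng: np.random.Generator, shape, alpha: float = 1.0, sd: float = 1.0) -> np.ndarray:
    """1/f^alpha noise along the last axis, expected per-sample std = sd."""
    shape = tuple(shape)
    n = shape[-1]
    if sd == 0.0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / SAMPLE_RATE_HZ)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-alpha / 2.0)  # DC removed
    # normalize so the shaped output has expected per-sample variance 1
    mult = np.full(len(f), 2.0)  # conjugate-symmetric bins count twice
    mult[0] = 1.0
    if n % 2 == 0:
        mult[-1] = 1.0  # Nyquist bin is real-valued
    norm = np.sqrt(np.sum(mult * gain**2) / n)
    spectrum *= gain / norm
    return sd * np.fft.irfft(spectrum, n=n, axis=-1)


def _epoch_signal(profile: SubjectProfile, frequency: float, is_target: bool,
                  rng: np.random.Generator) -> np.ndarray:
    """Noise-free (13, 200) signal for one flash."""
    t = np.arange(EPOCH_SAMPLES) / SAMPLE_RATE_HZ
    data = np.zeros((N_CHANNELS, EPOCH_SAMPLES))

    ssvep_gain = 1.0 if is_target else profile.nontarget_ssvep_gain
    if ssvep_gain > 0 and profile.ssvep_amplitude > 0:
        wave = np.zeros(EPOCH_SAMPLES)
        for h in range(1, profile.n_harmonics + 1):
            amp = profile.ssvep_amplitude * profile.harmonic_decay ** (h - 1)
            locked = np.sin(2 * np.pi * h * frequency * t)
            drift = np.sin(2 * np.pi * h * frequency * t + rng.uniform(0, 2 * np.pi))
            wave += amp * (profile.phase_locking * locked + (1 - profile.phase_locking) * drift)
        data += ssvep_gain * SSVEP_TOPOGRAPHY[:, None] * wave[None, :]

    if is_target and profile.p300_amplitude > 0:
        peak = profile.p300_latency + rng.normal(0.0, profile.latency_jitter_sd)
        bump = profile.p300_amplitude * np.exp(-0.5 * ((t - peak) / profile.p300_width) ** 2)
        data += P300_TOPOGRAPHY[:, None] * bump[None, :]

    return data


def simulate_flash_epoch(profile: SubjectProfile, line: LineID, is_target: bool,
                         seed: Optional[int] = None) -> FlashEpoch:
    """Simulate a single flash-locked epoch, reproducible under seed."""
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    return _simulate_epoch(profile, line, is_target, rng)


def _simulate_epoch(profile: SubjectProfile, line: LineID, is_target: bool,
                    rng: np.random.Generator, trial_id: int = 0, epoch_id: int = 0) -> FlashEpoch:
    freq = line_frequency(line)
    data = _epoch_signal(profile, freq, is_target, rng)
    data = data + pink_noise(rng, (N_CHANNELS, EPOCH_SAMPLES),
                             alpha=profile.noise_exponent, sd=profile.noise_sd)
    return FlashEpoch(data=data.astype(np.float32), line=line, frequency=freq,
                      is_target=is_target, trial_id=trial_id, epoch_id=epoch_id)


def _simulate_trial(profile: SubjectProfile, character: str, grid: CharacterGrid,
                    rng: np.random.Generator, trial_id: int, epoch_id: int) -> TrialRecord:
    row, col = grid.locate(character)
    schedule = make_trial_schedule(int(rng.integers(0, 2**31 - 1)))
    targets = {row.flat_index, col.flat_index}
    epochs = [
        _simulate_epoch(profile, line, line.flat_index in targets, rng, trial_id, epoch_id)
        for line in schedule.flashes
    ]
    return TrialRecord(epochs=epochs, character=character, schedule=schedule, trial_id=trial_id)


def simulate_calibration(profile: SubjectProfile, characters: Optional[Sequence[str]] = None,
                         grid: Optional[CharacterGrid] = None) -> SessionSet:
    """Simulate one calibration session: 11 blocks x 12 spelled characters.

    Target characters are drawn uniformly from the grid unless a list of
    132 characters is supplied. Yields 1,584 flash epochs with exactly
    2 target flashes per trial (1:5 target:non-target overall).
    """
    grid = grid or CharacterGrid()
    rng = np.random.default_rng(profile.seed)
    n_trials = CALIBRATION_BLOCKS * TRIALS_PER_BLOCK
    if characters is None:
        characters = [grid.symbols[i] for i in rng.integers(0, 36, size=n_trials)]
    elif len(characters) != n_trials:
        raise ValueError(f"need {n_trials} characters, got {len(characters)}")
    trials = [
        _simulate_trial(profile, characters[i], grid, rng,
                        trial_id=i, epoch_id=i // TRIALS_PER_BLOCK)
        for i in range(n_trials)
    ]
    return SessionSet(trials=trials, kind="calibration", profile=profile)


def simulate_copy_session(profile: SubjectProfile, text: str,
                          grid: Optional[CharacterGrid] = None) -> SessionSet:
    """Simulate copy-spelling of `text`: one trial per character, in order."""
    grid = grid or CharacterGrid()
    for ch in text:
        grid.locate(ch)  # raises KeyError if absent
    rng = np.random.default_rng(None if profile.seed is None else profile.seed + 1)
    trials = [
        _simulate_trial(profile, ch, grid, rng, trial_id=i, epoch_id=i // TRIALS_PER_BLOCK)
        for i, ch in enumerate(text)
    ]
    return SessionSet(trials=trials, kind="copy", profile=profile)
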