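"""Frequency-enhanced row/column (FERC) stimulus paradigm.

A 6x6 alphanumeric grid is spelled by flashing each of its 6 rows and
6 columns once per trial in pseudorandom order (an oddball sequence that
evokes a P300 to the two lines containing the attended character), while
every line simultaneously flickers at its own tagging frequency
(columns 6.0-8.5 Hz, rows 9.0-11.5 Hz, 0.5 Hz apart) to evoke an SSVEP.
This module models the grid, the line/frequency bookkeeping, the flash
schedule, and the flicker intensity waveform; it is the single source of
truth for the 12-line `flat_index` convention (columns 1-6, rows 7-12)
shared by both decoders and the fusion stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

GRID_ROWS: Sequence[str] = ("ABCDEF", "GHIJKL", "MNOPQR", "STUVWX", "YZ0123", "456789")

COLUMN_FREQUENCIES_HZ: Sequence[float] = (6.0, 6.5, 7.0, 7.5, 8.0, 8.5)
ROW_FREQUENCIES_HZ: Sequence[float] = (9.0, 9.5, 10.0, 10.5, 11.0, 11.5)

FLASH_DURATION_S = 1.0
INTER_FLASH_INTERVAL_S = 0.1
CUE_DURATION_S = 2.0

N_LINES = 12


@dataclass(frozen=True)
class LineID:
    """One of the 12 flashing lines: a row or a column, 1-based index."""

    kind: str  # "row" | "column"
    index: int  # 1..6

    def __post_init__(self) -> None:
        if self.kind not in ("row", "column"):
            raise ValueError(f"kind must be 'row' or 'column', got {self.kind!r}")
        if not 1 <= self.index <= 6:
            raise ValueError(f"line index must be in 1..6, got {self.index}")

    @property
    def flat_index(self) -> int:
        """Position in the shared 12-vector: columns 1-6, rows 7-12."""
        return self.index if self.kind == "column" else 6 + self.index

    @classmethod
    def from_flat(cls, flat_index: int) -> "LineID":
        if not 1 <= flat_index <= 12:
            raise ValueError(f"flat_index must be in 1..12, got {flat_index}")
        if flat_index <= 6:
            return cls("column", flat_index)
        return cls("row", flat_index - 6)


ALL_LINES: Sequence[LineID] = tuple(LineID.from_flat(i) for i in range(1, 13))


class CharacterGrid:
    """The 6x6 speller matrix: A-Z then 0-9, row-major."""

    def __init__(self, rows: Sequence[str] = GRID_ROWS):
        symbols = [ch for row in rows for ch in row]
        if len(symbols) != 36 or len(set(symbols)) != 36:
            raise ValueError("grid must contain exactly 36 distinct symbols")
        if any(len(row) != 6 for row in rows) or len(rows) != 6:
            raise ValueError("grid must be 6 rows of 6 symbols")
        self.rows: List[str] = list(rows)

    def symbol_at(self, row: int, column: int) -> str:
        """Symbol at 1-based (row, column)."""
        if not (1 <= row <= 6 and 1 <= column <= 6):
            raise ValueError("row and column must be in 1..6")
        return self.rows[row - 1][column - 1]

    def locate(self, symbol: str) -> tuple:
        """(row LineID, column LineID) of a symbol."""
        for r, row in enumerate(self.rows, start=1):
            c = row.find(symbol) + 1
            if c:
                return LineID("row", r), LineID("column", c)
        raise KeyError(f"symbol {symbol!r} not in grid")

    @property
    def symbols(self) -> List[str]:
        return [ch for row in self.rows for ch in row]


def build_frequency_map() -> Dict[LineID, float]:
    """Fixed line -> flicker frequency assignment (Hz).

    Columns 1-6 tag 6.0-8.5 Hz, rows 1-6 tag 9.0-11.5 Hz, all 0.5 Hz apart.
    """
    freqs: Dict[LineID, float] = {}
    for c, f in enumerate(COLUMN_FREQUENCIES_HZ, start=1):
        freqs[LineID("column", c)] = f
    for r, f in enumerate(ROW_FREQUENCIES_HZ, start=1):
        freqs[LineID("row", r)] = f
    return freqs


def line_frequency(line: LineID) -> float:
    """Flicker frequency (Hz) of a single line."""
    base, offset = (6.0, COLUMN_FREQUENCIES_HZ) if line.kind == "column" else (9.0, ROW_FREQUENCIES_HZ)
    return offset[line.index - 1]


def intensity(f: float, t) -> float:
    """Flicker background intensity (cos(2*pi*f*t)+1)/2 in [0, 1].

    The cosine guarantees the intensity is defined at every screen refresh
    instant regardless of phase between refresh and stimulus clock.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = (np.cos(2.0 * math.pi * f * t) + 1.0) / 2.0
    return float(out) if out.ndim == 0 else out


@dataclass
class TrialSchedule:
    """Pseudorandom order of the 12 line flashes for one spelled character."""

    flashes: List[LineID]
    flash_duration: float = FLASH_DURATION_S
    inter_flash_interval: float = INTER_FLASH_INTERVAL_S
    cue_duration: float = CUE_DURATION_S
    seed: int | None = None

    def __post_init__(self) -> None:
        if sorted(l.flat_index for l in self.flashes) != list(range(1, 13)):
            raise ValueError("schedule must flash each of the 12 lines exactly once")

    def onsets(self) -> np.ndarray:
        """Physical flash-onset times (s) within the trial, after the cue."""
        step = self.flash_duration + self.inter_flash_interval
        return self.cue_duration + step * np.arange(12)


def make_trial_schedule(seed: int | None = None) -> TrialSchedule:
    """Uniformly random permutation of the 12 lines, reproducible under seed."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(12)
    return TrialSchedule(flashes=[ALL_LINES[i] for i in order], seed=seed)


def target_from_lines(row: LineID, col: LineID, grid: CharacterGrid) -> str:
    """The spelled symbol at the intersection of a row flash and a column flash."""
    if row.kind != "row" or col.kind != "column":
        raise ValueError("expected a row LineID and a column LineID")
    return grid.symbol_at(row.index, col.index)


def schedule_event_table(
    schedule: TrialSchedule, target_row: LineID, target_col: LineID
) -> List[dict]:
    """Plain-record event table: one dict per flash.

    Onset seconds are physical (cue + flash + interval timing); flat_index,
    frequency and is_target flag give the decoder its epoching reference.
    """
    target_flats = {target_row.flat_index, target_col.flat_index}
    onsets = schedule.onsets()
    return [
        {
            "onset_s": float(onsets[i]),
            "flat_index": line.flat_index,
            "frequency_hz": line_frequency(line),
            "is_target": line.flat_index in target_flats,
        }
        for i, line in enumerate(schedule.flashes)
    ]
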