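"""Accuracy-weighted fusion of the P300 and SSVEP score vectors.

The controller weights each modality by its chance-corrected calibration
accuracy,

    w_P = (acc_P - E) / (acc_P + acc_S - 2E),   w_S = 1 - w_P,

with E = 1/36 the character-level accuracy of a fully random speller.
A modality at or below chance is clamped to weight 0. Because a
probability-like vector and a correlation vector live on different
scales, each 12-vector is z-scored and softmaxed before mixing; the
decoded column is the argmax over flat indices 1-6 and the decoded row
the argmax over 7-12 (ties break to the lowest index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .paradigm import CharacterGrid, LineID

CHANCE_CHARACTER_ACCURACY = 1.0 / 36.0


@dataclass
class FusionController:
    acc_P: float
    acc_S: float
    chance: float
    w_P: float
    w_S: float


@dataclass
class Decision:
    row: LineID
    column: LineID
    character: str
    combined_scores: np.ndarray


def fit_fusion(acc_P: float, acc_S: float, chance: float = CHANCE_CHARACTER_ACCURACY) -> FusionController:
    """Modality weights from calibration accuracies, chance-clamped."""
    exc_p = max(acc_P - chance, 0.0)
    exc_s = max(acc_S - chance, 0.0)
    if exc_p == 0.0 and exc_s == 0.0:
        raise ValueError("both modalities are at or below chance; fusion unusable")
    w_p = exc_p / (exc_p + exc_s)
    return FusionController(acc_P=acc_P, acc_S=acc_S, chance=chance, w_P=w_p, w_S=1.0 - w_p)


def _normalize(scores: np.ndarray) -> np.ndarray:
    """z-score then softmax; a constant vector maps to the uniform vector."""
    s = np.asarray(scores, dtype=float)
    sd = s.std()
    z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    e = np.exp(z - z.max())
    return e / e.sum()


def decide(combined: np.ndarray, grid: CharacterGrid) -> Decision:
    """Decode the character from a combined 12-vector (flat-index order)."""
    combined = np.asarray(combined, dtype=float)
    if combined.shape != (12,):
        raise ValueError("combined score vector must have length 12")
    col = LineID("column", int(np.argmax(combined[:6])) + 1)
    row = LineID("row", int(np.argmax(combined[6:])) + 1)
    return Decision(row=row, column=col,
                    character=grid.symbol_at(row.index, col.index),
                    combined_scores=combined)


def fuse(controller: FusionController, p_scores: np.ndarray, s_scores: np.ndarray,
         grid: CharacterGrid | None = None) -> Decision:
    """Weighted mix of normalized modality scores -> decoded character."""
    p_scores = np.asarray(p_scores, dtype=float)
    s_scores = np.asarray(s_scores, dtype=float)
    if p_scores.shape != (12,) or s_scores.shape != (12,):
        raise ValueError("both score vectors must have length 12")
    combined = controller.w_P * _normalize(p_scores) + controller.w_S * _normalize(s_scores)
    return decide(combined, grid or CharacterGrid())
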