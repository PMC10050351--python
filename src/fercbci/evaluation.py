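"""Accuracy, information transfer rate, confusion matrix, and the
calibration + copy-spelling experiment harness.

Accuracy is the fraction of correctly spelled characters, ACC =
100 * X1 / X. Speed is summarized by the Wolpaw information transfer
rate for an N-target selection taking T minutes at accuracy P:

    ITR = [log2 N + P log2 P + (1 - P) log2((1 - P)/(N - 1))] / T

in bits per minute, with the P -> 1 limit taken analytically. The
selection time used throughout is T = 0.16 min (9.6 s: twelve 0.8 s
analyzed epochs per character); the physical trial length, including
the 2 s cue and 100 ms inter-flash gaps, is reported alongside for
transparency but does not enter the ITR.

`run_experiment` reproduces the speller's protocol on synthetic EEG:
simulate an 11-block calibration session, train the P300 ensemble, the
ensemble-TRCA model and the fusion controller (all accuracies by
leave-one-block-out cross-validation), then decode copy-spelling of
three fixed strings repeated three times (81 characters) with the
hybrid decoder and each single modality, plus the CCA baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import p300 as p300_mod
from . import ssvep as ssvep_mod
from .fusion import CHANCE_CHARACTER_ACCURACY, Decision, decide, fit_fusion, fuse
from .paradigm import CharacterGrid, LineID
from .preprocess import ChannelSplit, preprocess_session, split_channels
from .synth import (
    CALIBRATION_BLOCKS,
    SubjectProfile,
    simulate_calibration,
    simulate_copy_session,
)

DEFAULT_SELECTION_TIME_MIN = 0.16  # 12 flashes x 0.8 s analyzed epoch
PHYSICAL_TRIAL_S = 2.0 + 12 * 1.1  # cue + 12 x (1 s flash + 0.1 s gap)
N_TARGETS = 36
COPY_TEXTS: Tuple[str, ...] = ("BCISPELLER", "HELLOWORLD", "NEUBMIE")


@dataclass
class ITRParams:
    n_targets: int = N_TARGETS
    p: float = 1.0
    t_minutes: float = DEFAULT_SELECTION_TIME_MIN


def itr(p: float, n_targets: int = N_TARGETS,
        t_minutes: float = DEFAULT_SELECTION_TIME_MIN) -> float:
    """Wolpaw information transfer rate in bits per minute."""
    if not 0.0 < p <= 1.0:
        raise ValueError("selection accuracy must lie in (0, 1]")
    if n_targets < 2 or t_minutes <= 0:
        raise ValueError("need n_targets >= 2 and positive selection time")
    bits = math.log2(n_targets)
    bits += p * math.log2(p) if p > 0 else 0.0
    if p < 1.0:
        bits += (1.0 - p) * math.log2((1.0 - p) / (n_targets - 1))
    return bits / t_minutes


def itr_from_params(params: ITRParams) -> float:
    return itr(params.p, params.n_targets, params.t_minutes)


@dataclass
class TrialOutcome:
    true_character: str
    true_row: LineID
    true_column: LineID
    decision: Decision

    @property
    def correct(self) -> bool:
        return self.decision.character == self.true_character


@dataclass
class SpellingResult:
    outcomes: List[TrialOutcome]

    @property
    def X(self) -> int:
        return len(self.outcomes)

    @property
    def X1(self) -> int:
        return sum(o.correct for o in self.outcomes)


def accuracy(result: SpellingResult) -> float:
    """Character accuracy ACC = 100 * X1 / X, in percent."""
    if result.X == 0:
        raise ValueError("empty spelling result")
    return 100.0 * result.X1 / result.X


def confusion_matrix(result: SpellingResult) -> np.ndarray:
    """12 x 12 line confusion counts: true flat index x decoded flat index.

    Column decisions populate the upper-left 6x6 block, row decisions the
    lower-right 6x6 block; the off-diagonal blocks stay empty because the
    two axes are decoded independently.
    """
    mat = np.zeros((12, 12), dtype=int)
    for o in result.outcomes:
        mat[o.true_column.flat_index - 1, o.decision.column.flat_index - 1] += 1
        mat[o.true_row.flat_index - 1, o.decision.row.flat_index - 1] += 1
    return mat


@dataclass
class ExperimentConfig:
    profile: SubjectProfile = field(default_factory=SubjectProfile)
    seed: int = 0
    texts: Sequence[str] = COPY_TEXTS
    repetitions: int = 3
    include_cca: bool = True
    selection_time_min: float = DEFAULT_SELECTION_TIME_MIN
    n_targets: int = N_TARGETS


def _ssvep_banked_session(preprocessed, split: ChannelSplit):
    """Stack SSVEP views of all epochs and filter-bank them once."""
    views, flats, labels, blocks, trial_ids = [], [], [], [], []
    for trial_epochs in preprocessed:
        for ep in trial_epochs:
            views.append(split_channels(ep, split)[1])
            flats.append(ep.line.flat_index)
            labels.append(ep.is_target)
            blocks.append(ep.epoch_id)
            trial_ids.append(ep.trial_id)
    return (np.stack(views), np.asarray(flats), np.asarray(labels, bool),
            np.asarray(blocks), np.asarray(trial_ids))


def _per_trial_vectors(scores_12: np.ndarray, flats: np.ndarray,
                       trial_ids: np.ndarray) -> Dict[int, np.ndarray]:
    """Own-epoch score vectors per trial from (E, 12) all-frequency scores."""
    vecs: Dict[int, np.ndarray] = {}
    for t in np.unique(trial_ids):
        mask = trial_ids == t
        vec = np.zeros(12)
        for i in np.flatnonzero(mask):
            vec[flats[i] - 1] = scores_12[i, flats[i] - 1]
        vecs[int(t)] = vec
    return vecs


def _ssvep_cv_accuracy(banked: np.ndarray, flats, labels, blocks, trial_ids,
                       truth_by_trial, bank) -> float:
    """Leave-one-block-out character accuracy of the TRCA decoder."""
    correct = total = 0
    for b in np.unique(blocks):
        train = blocks != b
        banked_by_line = {
            f: banked[train & labels & (flats == f)] for f in range(1, 13)
        }
        if any(v.shape[0] < 2 for v in banked_by_line.values()):
            raise ValueError("a line has fewer than 2 calibration target trials")
        model = ssvep_mod.fit_trca_banked(banked_by_line, bank)
        test = np.flatnonzero(~train)
        scores = model.score_epochs_banked(banked[test])
        vecs = _per_trial_vectors(scores, flats[test], trial_ids[test])
        for t, vec in vecs.items():
            true_col, true_row = truth_by_trial[t]
            ok = (int(np.argmax(vec[:6])) + 1 == true_col.index
                  and int(np.argmax(vec[6:])) + 1 == true_row.index)
            correct += bool(ok)
            total += 1
    return correct / total


def run_experiment(config: ExperimentConfig = ExperimentConfig()) -> dict:
    """Calibrate on synthetic EEG, decode copy-spelling, report ACC and ITR."""
    grid = CharacterGrid()
    split = ChannelSplit()
    profile = replace(config.profile, seed=config.seed)

    # --- calibration phase -------------------------------------------------
    calib = simulate_calibration(profile)
    calib_pre = preprocess_session(calib)

    rng = np.random.default_rng(config.seed)
    p300_model = p300_mod.train_ensemble(calib, seed=int(rng.integers(0, 2**31 - 1)),
                                         preprocessed=calib_pre, split=split)
    acc_P = p300_model.cv_character_accuracy

    bank = ssvep_mod.design_filter_bank()
    views, flats, labels, blocks, trial_ids = _ssvep_banked_session(calib_pre, split)
    banked = bank.apply(views)
    truth_by_trial = {
        t.trial_id: (grid.locate(t.character)[1], grid.locate(t.character)[0])
        for t in calib.trials
    }
    acc_S = _ssvep_cv_accuracy(banked, flats, labels, blocks, trial_ids,
                               truth_by_trial, bank)
    banked_by_line = {f: banked[labels & (flats == f)] for f in range(1, 13)}
    trca_model = ssvep_mod.fit_trca_banked(banked_by_line, bank, split=split)

    controller = fit_fusion(acc_P, acc_S, CHANCE_CHARACTER_ACCURACY)

    # --- copy-spelling phase ----------------------------------------------
    text = "".join(config.texts) * config.repetitions
    copy = simulate_copy_session(profile, text)
    copy_pre = preprocess_session(copy)

    c_views, c_flats, _, _, c_trials = _ssvep_banked_session(copy_pre, split)
    s_scores_all = trca_model.score_epochs_banked(bank.apply(c_views))
    s_vecs = _per_trial_vectors(s_scores_all, c_flats, c_trials)

    p_feats, _, _, p_flats, p_trials = p300_mod.session_features(
        copy, preprocessed=copy_pre, split=split)
    p_all = p300_model.epoch_scores(p_feats)
    p_vecs: Dict[int, np.ndarray] = {}
    for t in np.unique(p_trials):
        mask = p_trials == t
        vec = np.zeros(12)
        vec[p_flats[mask] - 1] = p_all[mask]
        p_vecs[int(t)] = vec

    results = {m: [] for m in ("hybrid", "p300", "ssvep", "cca")}
    for trial, trial_epochs in zip(copy.trials, copy_pre):
        true_row, true_col = grid.locate(trial.character)
        p_vec, s_vec = p_vecs[trial.trial_id], s_vecs[trial.trial_id]
        decisions = {
            "hybrid": fuse(controller, p_vec, s_vec, grid),
            "p300": decide(p_vec, grid),
            "ssvep": decide(s_vec, grid),
        }
        if config.include_cca:
            decisions["cca"] = decide(ssvep_mod.cca_score_trial(trial_epochs, split=split), grid)
        for m, d in decisions.items():
            results[m].append(TrialOutcome(trial.character, true_row, true_col, d))

    spelling = {m: SpellingResult(o) for m, o in results.items() if o}
    accs = {m: accuracy(r) for m, r in spelling.items()}
    # a modality that decoded nothing carries no information
    itrs = {m: (itr(a / 100.0, config.n_targets, config.selection_time_min)
                if a > 0 else 0.0)
            for m, a in accs.items()}

    return {
        "seed": config.seed,
        "n_trials": len(copy.trials),
        "acc_percent": accs,
        "itr_bits_per_min": itrs,
        "calibration": {
            "acc_P": acc_P,
            "acc_S": acc_S,
            "w_P": controller.w_P,
            "w_S": controller.w_S,
            "flash_cv_accuracies": p300_model.cv_accuracies.tolist(),
            "ensemble_weights": p300_model.weights.tolist(),
        },
        "confusion_hybrid": confusion_matrix(spelling["hybrid"]).tolist(),
        "selection_time_min": config.selection_time_min,
        "physical_trial_s": PHYSICAL_TRIAL_S,
        "spelling": spelling,
    }
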