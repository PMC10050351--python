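"""Single-trial P300 detection.

A flash epoch's 8-channel P300 view is reduced to 104 features: the 13
coarse (approximation) coefficients of a depth-4 Daubechies-4 discrete
wavelet transform per channel, concatenated channel-major. The DWT uses
periodized extension so the approximation chain is 200 -> 100 -> 50 ->
25 -> 13 samples, keeping only the low-frequency band where the P300
lives.

Because each trial has 2 target and 10 non-target flashes, training data
are 1:5 imbalanced. An EasyEnsemble-style scheme splits the non-target
samples into five disjoint parts, pairs each part with a copy of all
target samples, and trains one Gaussian-kernel SVM per balanced set.
The five classifiers are combined with chance-corrected weights

    w_m = (acc_m - P) / sum_i (acc_i - P)

over classifiers whose cross-validated accuracy acc_i exceeds the chance
level P (0.5 for the balanced binary problem); sub-chance classifiers
get weight 0. SVM margins are squashed to [0, 1] by a logistic sigmoid
fitted on training margins, and a trial's 12 ensemble scores (one per
flashed line) are reported at each line's flat index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pywt
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .preprocess import ChannelSplit, split_channels
from .synth import FlashEpoch

WAVELET = "db4"
DWT_LEVEL = 4
DWT_MODE = "periodization"
N_FEATURES_PER_CHANNEL = 13
N_P300_CHANNELS = 8
N_FEATURES = N_FEATURES_PER_CHANNEL * N_P300_CHANNELS  # 104
N_CLASSIFIERS = 5
CHANCE_LEVEL = 0.5  # balanced binary sub-problem


def extract_features(view: np.ndarray) -> np.ndarray:
    """104-dim wavelet feature vector from one 8 x 200 P300 view."""
    view = np.asarray(view, dtype=float)
    if view.shape != (N_P300_CHANNELS, 200):
        raise ValueError(f"expected (8, 200) view, got {view.shape}")
    return extract_features_batch(view[None, :, :])[0]


def extract_features_batch(views: np.ndarray) -> np.ndarray:
    """(N, 8, 200) -> (N, 104): depth-4 approximation coefficients per channel."""
    views = np.asarray(views, dtype=float)
    coeffs = pywt.wavedec(views, WAVELET, mode=DWT_MODE, level=DWT_LEVEL, axis=-1)
    approx = coeffs[0]  # (N, 8, 13)
    return approx.reshape(views.shape[0], -1)


def partition_training(labels: Sequence[bool], seed: Optional[int] = None) -> List[np.ndarray]:
    """Five balanced index sets: disjoint fifths of non-targets + all targets.

    Returns index arrays into the sample axis; the union of the non-target
    portions is exactly the non-target multiset.
    """
    y = np.asarray(labels, dtype=bool)
    tss = np.flatnonzero(y)
    nss = np.flatnonzero(~y)
    if len(tss) == 0 or len(nss) == 0:
        raise ValueError("both target and non-target samples are required")
    rng = np.random.default_rng(seed)
    parts = np.array_split(rng.permutation(nss), N_CLASSIFIERS)
    return [np.concatenate([tss, part]) for part in parts]


def ensemble_weights(cv_accuracies: Sequence[float], chance: float = CHANCE_LEVEL) -> np.ndarray:
    """Chance-corrected simplex weights; sub-chance classifiers clamped to 0."""
    accs = np.asarray(cv_accuracies, dtype=float)
    excess = accs - chance
    excess[excess <= 0] = 0.0
    total = excess.sum()
    if total <= 0:
        raise ValueError("all classifiers are at or below chance; ensemble unusable")
    return excess / total


def _median_heuristic_gamma(X: np.ndarray, rng: np.random.Generator) -> float:
    """RBF bandwidth: gamma = 1 / (2 * median squared pairwise distance)."""
    n = X.shape[0]
    sub = X[rng.choice(n, size=min(n, 200), replace=False)]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    d2 = d2[np.triu_indices_from(d2, k=1)]
    d2 = d2[d2 > 0]
    if d2.size == 0:
        return 1.0 / X.shape[1]
    return 1.0 / (2.0 * float(np.median(d2)))


@dataclass
class _CalibratedSVM:
    """Gaussian-kernel SVM plus a logistic squashing of its margin."""

    svm: SVC
    sigmoid: LogisticRegression

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        margins = self.svm.decision_function(X)
        return self.sigmoid.predict_proba(margins[:, None])[:, 1]


def _fit_calibrated_svm(X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> _CalibratedSVM:
    gamma = _median_heuristic_gamma(X, rng)
    svm = SVC(kernel="rbf", gamma=gamma, C=1.0)
    svm.fit(X, y)
    margins = svm.decision_function(X)
    sigmoid = LogisticRegression(C=1e3)
    sigmoid.fit(margins[:, None], y)
    return _CalibratedSVM(svm=svm, sigmoid=sigmoid)


def _fit_subclassifiers(X: np.ndarray, y: np.ndarray, seed) -> List[_CalibratedSVM]:
    rng = np.random.default_rng(seed)
    sets = partition_training(y, seed=int(rng.integers(0, 2**31 - 1)))
    return [_fit_calibrated_svm(X[idx], y[idx], rng) for idx in sets]


@dataclass
class EnsembleSVMModel:
    """Five calibrated SVMs with chance-corrected ensemble weights."""

    classifiers: List[_CalibratedSVM]
    cv_accuracies: np.ndarray
    chance_level: float
    weights: np.ndarray
    cv_character_accuracy: float = float("nan")
    split: ChannelSplit = field(default_factory=ChannelSplit)

    def epoch_scores(self, features: np.ndarray) -> np.ndarray:
        """(N, 104) features -> (N,) weighted ensemble scores in [0, 1]."""
        probs = np.stack([clf.predict_proba(features) for clf in self.classifiers], axis=1)
        return probs @ self.weights


def session_features(session, preprocessed=None, split: ChannelSplit = ChannelSplit()):
    """Features/labels/block/flat arrays for every flash of a session."""
    from .preprocess import preprocess_session

    trials = preprocessed if preprocessed is not None else preprocess_session(session)
    views, labels, blocks, flats, trial_ids = [], [], [], [], []
    for trial_epochs in trials:
        for ep in trial_epochs:
            p_view, _ = split_channels(ep, split)
            views.append(p_view)
            labels.append(ep.is_target)
            blocks.append(ep.epoch_id)
            flats.append(ep.line.flat_index)
            trial_ids.append(ep.trial_id)
    X = extract_features_batch(np.stack(views))
    return (X, np.asarray(labels, bool), np.asarray(blocks), np.asarray(flats),
            np.asarray(trial_ids))


def train_ensemble(session, seed: Optional[int] = None, preprocessed=None,
                   split: ChannelSplit = ChannelSplit()) -> EnsembleSVMModel:
    """Train the weighted SVM ensemble on a calibration session.

    Per-classifier accuracies come from leave-one-block-out cross-validation
    over the 11 calibration blocks; the character-level cross-validated
    accuracy (used later by the fusion controller) is computed from the
    same held-out scores.
    """
    X, y, blocks, flats, trial_ids = session_features(session, preprocessed, split)
    if y.all() or not y.any():
        raise ValueError("calibration session must contain both classes")
    rng = np.random.default_rng(seed)

    held_out = np.full((len(y), N_CLASSIFIERS), np.nan)
    for b in np.unique(blocks):
        train = blocks != b
        clfs = _fit_subclassifiers(X[train], y[train], int(rng.integers(0, 2**31 - 1)))
        test = ~train
        for i, clf in enumerate(clfs):
            held_out[test, i] = clf.predict_proba(X[test])

    cv_accs = np.mean((held_out > 0.5) == y[:, None], axis=0)
    weights = ensemble_weights(cv_accs, CHANCE_LEVEL)

    # character-level CV accuracy: per trial, argmax over columns and rows
    ens = held_out @ weights
    correct = total = 0
    for t in np.unique(trial_ids):
        mask = trial_ids == t
        vec = np.zeros(12)
        vec[flats[mask] - 1] = ens[mask]
        truth = np.zeros(12, bool)
        truth[flats[mask][y[mask]] - 1] = True
        ok = truth[int(np.argmax(vec[:6]))] and truth[6 + int(np.argmax(vec[6:]))]
        correct += bool(ok)
        total += 1
    cv_char_acc = correct / total

    final = _fit_subclassifiers(X, y, int(rng.integers(0, 2**31 - 1)))
    return EnsembleSVMModel(classifiers=final, cv_accuracies=cv_accs,
                            chance_level=CHANCE_LEVEL, weights=weights,
                            cv_character_accuracy=cv_char_acc, split=split)


def score_trial(model: EnsembleSVMModel, epochs: List[FlashEpoch]) -> np.ndarray:
    """12-vector of ensemble P300 scores, one per line at its flat index."""
    flats = [ep.line.flat_index for ep in epochs]
    if sorted(flats) != list(range(1, 13)):
        raise ValueError("trial must contain one epoch per line")
    views = np.stack([split_channels(ep, model.split)[0] for ep in epochs])
    scores = model.epoch_scores(extract_features_batch(views))
    vec = np.zeros(12)
    vec[np.asarray(flats) - 1] = scores
    return vec
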