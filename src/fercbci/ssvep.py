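"""SSVEP detection: filter bank + ensemble task-related component analysis.

The 9-channel occipital view is decomposed by a bank of 10 Chebyshev-I
band-pass filters, sub-band k spanning [k*fa - 2, 90] Hz (fa = 8 Hz, the
2 Hz margin guards against edge distortion at the fundamental). Within
each sub-band, TRCA estimates one spatial filter per stimulus frequency:
with A the trial-averaged template and B the trial-stacked calibration
data at that frequency, the filter maximizes the Rayleigh quotient

    w* = argmax_w (w^T A^T A w) / (w^T B^T B w),

i.e. the ratio of reproducible (template) power to total power — the
leading generalized eigenvector of (A^T A, B^T B). The ensemble variant
projects test data and templates through the stacked 12-filter matrix W
and scores frequency f by the Pearson correlation between the two
projections; sub-band correlations are combined as
sum_k w(k) * sign(rho_k) * rho_k^2 with w(k) = k^-1.25 + 0.25.

A canonical-correlation (CCA) baseline against sine/cosine reference
sets is included for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import linalg, signal

from .paradigm import ALL_LINES, line_frequency
from .preprocess import ChannelSplit, split_channels
from .synth import EPOCH_SAMPLES, FlashEpoch, SAMPLE_RATE_HZ

N_SSVEP_CHANNELS = 9
N_BANDS = 10
DEFAULT_FA = 8.0
UPPER_EDGE_HZ = 90.0

ALL_FREQUENCIES = tuple(line_frequency(l) for l in ALL_LINES)  # flat order 1..12


@dataclass
class FilterBank:
    """Ten zero-phase Chebyshev-I band-pass filters, [k*fa - 2, 90] Hz."""

    sos: List[np.ndarray]
    band_edges: List[tuple]
    weights: np.ndarray  # sub-band combination weights w(k)
    fa: float
    fs: float

    def apply(self, data: np.ndarray) -> np.ndarray:
        """(..., ns) -> (..., n_bands, ns), filtered along the last axis."""
        data = np.asarray(data, dtype=float)
        out = np.empty(data.shape[:-1] + (len(self.sos), data.shape[-1]), dtype=np.float32)
        for k, sos in enumerate(self.sos):
            out[..., k, :] = signal.sosfiltfilt(sos, data, axis=-1)
        return out


def design_filter_bank(fa: float = DEFAULT_FA, fs: float = SAMPLE_RATE_HZ,
                       n_bands: int = N_BANDS, order: int = 4,
                       ripple_db: float = 0.5) -> FilterBank:
    """Chebyshev-I filter bank with sub-bands [k*fa - 2, 90] Hz, k = 1..n_bands."""
    if fa <= 2:
        raise ValueError("fa must exceed 2 Hz (the low-side widening)")
    nyq = fs / 2.0
    if UPPER_EDGE_HZ >= nyq:
        raise ValueError("upper band edge must lie below Nyquist")
    sos_list, edges = [], []
    for k in range(1, n_bands + 1):
        lo = k * fa - 2.0
        if lo >= UPPER_EDGE_HZ:
            raise ValueError(f"sub-band {k} lower edge {lo} Hz >= {UPPER_EDGE_HZ} Hz")
        sos_list.append(signal.cheby1(order, ripple_db, [lo, UPPER_EDGE_HZ],
                                      btype="bandpass", fs=fs, output="sos"))
        edges.append((lo, UPPER_EDGE_HZ))
    weights = np.array([k ** (-1.25) + 0.25 for k in range(1, n_bands + 1)])
    return FilterBank(sos=sos_list, band_edges=edges, weights=weights, fa=fa, fs=fs)


def trca_filter(trials: np.ndarray, ridge: float = 1e-6):
    """Spatial filter and template from (Nt, Ns, Nc) calibration trials.

    Returns (w, A): the unit-norm leading generalized eigenvector of
    (A^T A, B^T B + ridge) with sign fixed so its largest-magnitude entry
    is positive, and the trial-averaged template A (Ns, Nc).
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3 or trials.shape[0] < 2:
        raise ValueError("need at least 2 trials of shape (Ns, Nc)")
    n_t, n_s, n_c = trials.shape
    A = trials.mean(axis=0)
    M1 = A.T @ A
    B = trials.reshape(n_t * n_s, n_c)
    M2 = B.T @ B
    M2 = M2 + (ridge * np.trace(M2) / n_c) * np.eye(n_c)
    eigvals, eigvecs = linalg.eigh(M1, M2)
    w = eigvecs[:, -1]
    w = w / np.linalg.norm(w)
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return w, A


@dataclass
class TRCAModel:
    """Per-frequency spatial filters and templates, per sub-band."""

    filters: np.ndarray  # (n_bands, 12, Nc)
    templates: np.ndarray  # (n_bands, 12, Ns, Nc)
    bank: FilterBank
    ensemble: bool = True
    split: ChannelSplit = field(default_factory=ChannelSplit)

    def ensemble_matrix(self, band: int) -> np.ndarray:
        """(Nc, 12) stacked filter matrix W for one sub-band."""
        return self.filters[band].T

    def score_epochs(self, views: np.ndarray) -> np.ndarray:
        """(E, 9, 200) test views -> (E, 12) combined correlation scores."""
        views = np.asarray(views, dtype=float)
        if views.ndim == 2:
            views = views[None]
        return self.score_epochs_banked(self.bank.apply(views))

    def score_epochs_banked(self, banked: np.ndarray) -> np.ndarray:
        """Score already filter-banked views of shape (E, 9, n_bands, 200)."""
        scores = np.zeros((banked.shape[0], 12))
        for k in range(len(self.bank.sos)):
            Xk = np.swapaxes(banked[:, :, k, :], 1, 2)  # (E, Ns, Nc)
            rho = self._band_correlations(np.asarray(Xk, dtype=float), k)  # (E, 12)
            scores += self.bank.weights[k] * np.sign(rho) * rho**2
        return scores

    def _band_correlations(self, X: np.ndarray, band: int) -> np.ndarray:
        """Pearson corr between projected test data and each template."""
        if self.ensemble:
            W = self.ensemble_matrix(band)  # (Nc, 12)
            xp = (X @ W).reshape(X.shape[0], -1)  # (E, Ns*12)
            tp = (self.templates[band] @ W).reshape(12, -1)  # (12, Ns*12)
            return _rowwise_corr(xp, tp)
        rho = np.empty((X.shape[0], 12))
        for f in range(12):
            w = self.filters[band, f]
            xp = X @ w  # (E, Ns)
            tp = (self.templates[band, f] @ w)[None, :]  # (1, Ns)
            rho[:, f] = _rowwise_corr(xp, tp)[:, 0]
        return rho


def _rowwise_corr(X: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Correlation matrix (rows of X) x (rows of T); zero-variance rows -> 0."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    tn = np.linalg.norm(Tc, axis=1)
    denom = np.outer(xn, tn)
    out = np.zeros((X.shape[0], T.shape[0]))
    ok = denom > 0
    np.divide(Xc @ Tc.T, denom, out=out, where=ok)
    return out


def fit_trca(views_by_line: Dict[int, np.ndarray], bank: Optional[FilterBank] = None,
             ridge: float = 1e-6, ensemble: bool = True,
             split: ChannelSplit = ChannelSplit()) -> TRCAModel:
    """Fit the ensemble TRCA model.

    `views_by_line` maps each flat line index 1..12 to the (Nt, 9, 200)
    stack of calibration epochs recorded while that line's frequency was
    attended (the target flashes of that line).
    """
    bank = bank or design_filter_bank()
    missing = [f for f in range(1, 13) if f not in views_by_line]
    if missing:
        raise ValueError(f"missing calibration trials for lines {missing}")
    banked_by_line = {flat: bank.apply(np.asarray(views_by_line[flat], dtype=float))
                      for flat in range(1, 13)}
    return fit_trca_banked(banked_by_line, bank, ridge=ridge, ensemble=ensemble, split=split)


def fit_trca_banked(banked_by_line: Dict[int, np.ndarray], bank: FilterBank,
                    ridge: float = 1e-6, ensemble: bool = True,
                    split: ChannelSplit = ChannelSplit()) -> TRCAModel:
    """Fit TRCA from already filter-banked views, (Nt, 9, n_bands, 200) per line."""
    n_bands = len(bank.sos)
    filters = np.zeros((n_bands, 12, N_SSVEP_CHANNELS))
    templates = np.zeros((n_bands, 12, EPOCH_SAMPLES, N_SSVEP_CHANNELS))
    for flat in range(1, 13):
        banked = np.asarray(banked_by_line[flat], dtype=float)
        for k in range(n_bands):
            Z = np.swapaxes(banked[:, :, k, :], 1, 2)  # (Nt, Ns, Nc)
            w, A = trca_filter(Z, ridge=ridge)
            filters[k, flat - 1] = w
            templates[k, flat - 1] = A
    return TRCAModel(filters=filters, templates=templates, bank=bank,
                     ensemble=ensemble, split=split)


def target_views_by_line(preprocessed_trials: List[List[FlashEpoch]],
                         split: ChannelSplit = ChannelSplit()) -> Dict[int, np.ndarray]:
    """Group target-flash SSVEP views of a session by flat line index."""
    groups: Dict[int, list] = {f: [] for f in range(1, 13)}
    for trial_epochs in preprocessed_trials:
        for ep in trial_epochs:
            if ep.is_target:
                groups[ep.line.flat_index].append(split_channels(ep, split)[1])
    return {f: np.stack(v) for f, v in groups.items() if v}


def score_epoch(model: TRCAModel, view: np.ndarray) -> np.ndarray:
    """12-vector of combined correlation scores for one 9 x 200 view."""
    view = np.asarray(view, dtype=float)
    if view.shape != (N_SSVEP_CHANNELS, EPOCH_SAMPLES):
        raise ValueError(f"expected (9, 200) view, got {view.shape}")
    return model.score_epochs(view[None])[0]


def score_trial(model: TRCAModel, epochs: List[FlashEpoch]) -> np.ndarray:
    """Per-line SSVEP scores: each flashed line judged by its own epoch."""
    flats = [ep.line.flat_index for ep in epochs]
    if sorted(flats) != list(range(1, 13)):
        raise ValueError("trial must contain one epoch per line")
    views = np.stack([split_channels(ep, model.split)[1] for ep in epochs])
    all_scores = model.score_epochs(views)  # (12, 12)
    vec = np.zeros(12)
    for i, flat in enumerate(flats):
        vec[flat - 1] = all_scores[i, flat - 1]
    return vec


def _reference_set(frequency: float, n_harmonics: int, n_samples: int = EPOCH_SAMPLES,
                   fs: float = SAMPLE_RATE_HZ) -> np.ndarray:
    t = np.arange(n_samples) / fs
    cols = []
    for h in range(1, n_harmonics + 1):
        cols.append(np.sin(2 * np.pi * h * frequency * t))
        cols.append(np.cos(2 * np.pi * h * frequency * t))
    return np.stack(cols, axis=1)  # (Ns, 2H)


def _orthonormal_basis(M: np.ndarray) -> np.ndarray:
    """Rank-revealing orthonormal basis of the column space (SVD-based)."""
    u, s, _ = np.linalg.svd(M, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        return u[:, :0]
    return u[:, s > s[0] * 1e-10]


def canonical_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """Largest canonical correlation between column spaces of X and Y."""
    ux = _orthonormal_basis(X - X.mean(axis=0))
    uy = _orthonormal_basis(Y - Y.mean(axis=0))
    if ux.shape[1] == 0 or uy.shape[1] == 0:
        return 0.0
    s = np.linalg.svd(ux.T @ uy, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


def cca_scores(view: np.ndarray, frequencies: Sequence[float] = ALL_FREQUENCIES,
               n_harmonics: int = 3) -> np.ndarray:
    """CCA baseline: max canonical correlation per stimulus frequency."""
    view = np.asarray(view, dtype=float)
    X = view.T  # (Ns, Nc)
    return np.array([canonical_correlation(X, _reference_set(f, n_harmonics))
                     for f in frequencies])


def cca_score_trial(epochs: List[FlashEpoch], n_harmonics: int = 3,
                    split: ChannelSplit = ChannelSplit()) -> np.ndarray:
    """Per-line CCA scores, each flashed line judged by its own epoch."""
    vec = np.zeros(12)
    for ep in epochs:
        flat = ep.line.flat_index
        view = split_channels(ep, split)[1]
        vec[flat - 1] = cca_scores(view, frequencies=[ep.frequency], n_harmonics=n_harmonics)[0]
    return vec
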