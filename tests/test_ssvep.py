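import numpy as np
import pytest
from scipy import signal as sps

from fercbci import ssvep
from fercbci.paradigm import LineID
from fercbci.preprocess import preprocess_session, split_channels
from fercbci.synth import (
    SAMPLE_RATE_HZ,
    SubjectProfile,
    simulate_copy_session,
    simulate_flash_epoch,
)


def rayleigh_quotient(w, trials):
    A = trials.mean(axis=0)
    B = trials.reshape(-1, trials.shape[2])
    num = w @ (A.T @ A) @ w
    den = w @ (B.T @ B) @ w
    return num / den


def brute_force_max_quotient(trials, n_draws=10_000, seed=0):
    """Random-direction search oracle for the TRCA Rayleigh quotient."""
    rng = np.random.default_rng(seed)
    A = trials.mean(axis=0)
    B = trials.reshape(-1, trials.shape[2])
    M1, M2 = A.T @ A, B.T @ B
    W = rng.standard_normal((n_draws, trials.shape[2]))
    num = np.einsum("ij,jk,ik->i", W, M1, W)
    den = np.einsum("ij,jk,ik->i", W, M2, W)
    return (num / den).max()


class TestFilterBank:
    def test_band_edges(self):
        bank = ssvep.design_filter_bank(fa=8.0)
        assert bank.band_edges[0] == (6.0, 90.0)
        assert bank.band_edges[9] == (78.0, 90.0)
        assert len(bank.sos) == 10

    def test_stopband_and_passband(self):
        bank = ssvep.design_filter_bank()
        t = np.arange(1000) / SAMPLE_RATE_HZ
        stop = sps.sosfiltfilt(bank.sos[0], np.sin(2 * np.pi * 100.0 * t))
        keep = sps.sosfiltfilt(bank.sos[0], np.sin(2 * np.pi * 30.0 * t))
        mid = slice(200, -200)
        assert np.sqrt((stop[mid] ** 2).mean()) < 0.1 * np.sqrt(0.5)
        # forward-backward application doubles the 0.5 dB passband ripple,
        # so troughs sit ~11% below unity
        assert np.sqrt((keep[mid] ** 2).mean()) == pytest.approx(np.sqrt(0.5), rel=0.12)

    def test_rejects_band_past_upper_edge(self):
        with pytest.raises(ValueError):
            ssvep.design_filter_bank(fa=10.0)  # band 10 lower edge 98 >= 90


class TestTRCAFilter:
    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            trials = rng.standard_normal((4, 50, 3))
            w, _ = ssvep.trca_filter(trials, ridge=0.0)
            q = rayleigh_quotient(w, trials)
            q_star = brute_force_max_quotient(trials)
            assert q >= q_star - 1e-6 * abs(q_star)

    def test_identical_trials(self):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((60, 3))
        trials = np.stack([Z] * 4)
        w, A = ssvep.trca_filter(trials, ridge=0.0)
        np.testing.assert_allclose(A, Z, atol=1e-12)
        q = rayleigh_quotient(w, trials)
        assert q >= brute_force_max_quotient(trials) - 1e-6

    def test_consistent_channel_gets_weight(self):
        rng = np.random.default_rng(2)
        t = np.arange(200) / SAMPLE_RATE_HZ
        consistent = np.sin(2 * np.pi * 9.0 * t)
        trials = np.stack([
            np.stack([consistent, rng.standard_normal(200)], axis=1)
            for _ in range(8)
        ])
        w, _ = ssvep.trca_filter(trials)
        assert abs(w[0]) >= 5 * abs(w[1])

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        trials = rng.standard_normal((5, 80, 4))
        perm = [2, 0, 3, 1]
        w1, _ = ssvep.trca_filter(trials)
        w2, _ = ssvep.trca_filter(trials[:, :, perm])
        np.testing.assert_allclose(w2, w1[perm], atol=1e-8)

    def test_template_is_exact_trial_mean(self):
        trials = np.arange(2 * 6 * 3).reshape(2, 6, 3).astype(float)
        _, A = ssvep.trca_filter(trials)
        np.testing.assert_array_equal(A, trials.mean(axis=0))

    def test_rejects_single_trial(self):
        with pytest.raises(ValueError):
            ssvep.trca_filter(np.zeros((1, 10, 2)))


class TestScoring:
    def test_self_correlation_is_one(self, noiseless_trca_model):
        model = noiseless_trca_model
        X = model.templates[0, 3]  # (Ns, Nc), already filtered
        rho = model._band_correlations(X[None], band=0)
        assert rho[0, 3] == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_projection_scores_zero(self):
        xp = np.array([[1.0, -1.0, 1.0, -1.0]])
        tp = np.array([[1.0, 1.0, -1.0, -1.0]])
        assert ssvep._rowwise_corr(xp, tp)[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_scores_zero(self):
        assert ssvep._rowwise_corr(np.zeros((1, 8)), np.ones((1, 8)))[0, 0] == 0.0

    def test_noiseless_epoch_identified(self, noiseless_trca_model, noiseless_profile):
        # row 4 flickers at 10.5 Hz; its epoch must win all 12 scores
        ep = simulate_flash_epoch(noiseless_profile, LineID("row", 4), True, seed=99)
        view = split_channels(ep)[1]
        scores = ssvep.score_epoch(noiseless_trca_model, view)
        assert np.argmax(scores) == LineID("row", 4).flat_index - 1

    def test_scale_invariance(self, noiseless_trca_model, noiseless_profile):
        ep = simulate_flash_epoch(noiseless_profile, LineID("column", 1), True, seed=5)
        view = split_channels(ep)[1]
        a = ssvep.score_epoch(noiseless_trca_model, view)
        b = ssvep.score_epoch(noiseless_trca_model, 3.7 * view)
        np.testing.assert_allclose(a, b, atol=1e-4)  # float32 filtering path

    def test_noiseless_trial_spells_character(self, noiseless_trca_model,
                                              noiseless_profile, grid):
        session = simulate_copy_session(noiseless_profile, "K")
        epochs = preprocess_session(session)[0]
        vec = ssvep.score_trial(noiseless_trca_model, epochs)
        row, col = grid.locate("K")
        assert np.argmax(vec[:6]) + 1 == col.index
        assert np.argmax(vec[6:]) + 1 == row.index

    def test_pure_noise_trial_has_flat_scores(self, noiseless_trca_model,
                                              noiseless_profile):
        signal_sess = simulate_copy_session(noiseless_profile, "K")
        noise_profile = SubjectProfile(p300_amplitude=0.0, ssvep_amplitude=0.0,
                                       noise_sd=8.0, seed=13)
        noise_sess = simulate_copy_session(noise_profile, "K")
        spread = {}
        for name, sess in (("signal", signal_sess), ("noise", noise_sess)):
            vec = ssvep.score_trial(noiseless_trca_model, preprocess_session(sess)[0])
            spread[name] = vec.max() - np.median(vec)
        assert spread["noise"] * 5 <= spread["signal"]


class TestCCABaseline:
    def test_pure_sine_identified(self):
        t = np.arange(200) / SAMPLE_RATE_HZ
        view = np.zeros((9, 200))
        view[4] = np.sin(2 * np.pi * 8.0 * t)  # column 5 frequency
        scores = ssvep.cca_scores(view)
        assert np.argmax(scores) == LineID("column", 5).flat_index - 1

    def test_correlations_bounded(self):
        rng = np.random.default_rng(0)
        scores = ssvep.cca_scores(rng.standard_normal((9, 200)))
        assert np.all((scores >= 0.0) & (scores <= 1.0))
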