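import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fercbci import p300
from fercbci.synth import SAMPLE_RATE_HZ, SubjectProfile, simulate_calibration


class TestWaveletFeatures:
    def test_length_104(self):
        rng = np.random.default_rng(0)
        feats = p300.extract_features(rng.standard_normal((8, 200)))
        assert feats.shape == (104,)
        assert np.isfinite(feats).all()

    def test_zero_input_zero_features(self):
        assert np.allclose(p300.extract_features(np.zeros((8, 200))), 0.0)

    def test_low_frequency_energy_dominates(self):
        # approximation coefficients keep the low band: a 2 Hz tone must
        # yield far more feature energy than an equal-RMS 50 Hz tone
        t = np.arange(200) / SAMPLE_RATE_HZ
        slow = np.tile(np.sin(2 * np.pi * 2.0 * t), (8, 1))
        fast = np.tile(np.sin(2 * np.pi * 50.0 * t), (8, 1))
        e_slow = np.sum(p300.extract_features(slow) ** 2)
        e_fast = np.sum(p300.extract_features(fast) ** 2)
        assert e_slow > 5 * e_fast

    def test_rejects_wrong_shape(self):
        with pytest.raises(ValueError):
            p300.extract_features(np.zeros((9, 200)))


class TestPartition:
    def test_balanced_fifths(self):
        # one calibration session: 264 targets, 1320 non-targets
        y = np.array([True] * 264 + [False] * 1320)
        sets = p300.partition_training(y, seed=0)
        assert len(sets) == 5
        for idx in sets:
            assert (y[idx]).sum() == 264 and (~y[idx]).sum() == 264

    def test_nontarget_parts_exhaust_nss(self):
        y = np.array([True] * 20 + [False] * 100)
        sets = p300.partition_training(y, seed=1)
        nss_parts = np.concatenate([idx[~y[idx]] for idx in sets])
        assert sorted(nss_parts) == list(range(20, 120))

    def test_deterministic(self):
        y = np.array([True] * 10 + [False] * 50)
        a = p300.partition_training(y, seed=7)
        b = p300.partition_training(y, seed=7)
        for i, j in zip(a, b):
            np.testing.assert_array_equal(i, j)

    def test_rejects_single_class(self):
        with pytest.raises(ValueError):
            p300.partition_training(np.zeros(10, dtype=bool))


class TestEnsembleWeights:
    @pytest.mark.parametrize("accs,chance,expected", [
        ((0.7, 0.7, 0.7, 0.7, 0.7), 0.5, (0.2,) * 5),
        ((0.9, 0.6), 0.5, (0.8, 0.2)),
        ((0.9, 0.4), 0.5, (1.0, 0.0)),  # sub-chance classifier excluded
    ])
    def test_examples(self, accs, chance, expected):
        np.testing.assert_allclose(p300.ensemble_weights(accs, chance), expected,
                                   atol=1e-12)

    def test_all_subchance_raises(self):
        with pytest.raises(ValueError):
            p300.ensemble_weights((0.4, 0.5, 0.3), 0.5)

    @settings(derandomize=True, max_examples=300)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=8),
           st.floats(0.0, 0.9))
    def test_simplex_and_monotone(self, accs, chance):
        accs = np.asarray(accs)
        if not (accs > chance).any():
            with pytest.raises(ValueError):
                p300.ensemble_weights(accs, chance)
            return
        w = p300.ensemble_weights(accs, chance)
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()
        order = np.argsort(accs)
        assert (np.diff(w[order]) >= -1e-12).all()  # higher acc, never lower weight
        assert (w[accs <= chance] == 0).all()

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.05, 1.0), min_size=2, max_size=8))
    def test_zero_chance_reduces_to_proportional(self, accs):
        # with P = 0 the chance-corrected rule is plain accuracy weighting
        accs = np.asarray(accs)
        np.testing.assert_allclose(p300.ensemble_weights(accs, 0.0),
                                   accs / accs.sum(), atol=1e-12)


class TestEnsembleTraining:
    def test_noiseless_accuracies_high(self, noiseless_p300_model):
        assert (noiseless_p300_model.cv_accuracies >= 0.95).all()
        assert noiseless_p300_model.weights.sum() == pytest.approx(1.0)

    def test_training_deterministic(self, noiseless_calibration, noiseless_preprocessed):
        again = p300.train_ensemble(noiseless_calibration, seed=3,
                                    preprocessed=noiseless_preprocessed)
        ref = p300.train_ensemble(noiseless_calibration, seed=3,
                                  preprocessed=noiseless_preprocessed)
        np.testing.assert_array_equal(again.weights, ref.weights)
        np.testing.assert_array_equal(again.cv_accuracies, ref.cv_accuracies)

    def test_label_shuffle_yields_chance(self):
        session = simulate_calibration(SubjectProfile(seed=21))
        rng = np.random.default_rng(0)
        labels = np.array([ep.is_target for ep in session.all_epochs()])
        rng.shuffle(labels)
        i = 0
        for trial in session.trials:
            for ep in trial.epochs:
                ep.is_target = bool(labels[i])
                i += 1
        try:
            model = p300.train_ensemble(session, seed=1)
        except ValueError:
            return  # every classifier at or below chance: acceptable outcome
        assert np.all(np.abs(model.cv_accuracies - 0.5) <= 0.1)


class TestTrialScoring:
    def test_noiseless_targets_score_highest(self, noiseless_p300_model,
                                             noiseless_calibration,
                                             noiseless_preprocessed, grid):
        hits = 0
        for trial, epochs in zip(noiseless_calibration.trials[:20],
                                 noiseless_preprocessed[:20]):
            vec = p300.score_trial(noiseless_p300_model, epochs)
            row, col = grid.locate(trial.character)
            top_two = set(np.argsort(vec)[-2:] + 1)
            hits += top_two == {row.flat_index, col.flat_index}
        assert hits == 20

    def test_single_classifier_weight_degenerates(self, noiseless_p300_model,
                                                  noiseless_preprocessed):
        import copy
        model = copy.copy(noiseless_p300_model)
        model.weights = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        epochs = noiseless_preprocessed[0]
        vec = p300.score_trial(model, epochs)
        feats = p300.extract_features_batch(np.stack(
            [p300.split_channels(ep, model.split)[0] for ep in epochs]))
        solo = model.classifiers[0].predict_proba(feats)
        flats = np.array([ep.line.flat_index for ep in epochs])
        np.testing.assert_allclose(vec[flats - 1], solo, atol=1e-12)

    def test_identical_epochs_equal_scores(self, noiseless_p300_model,
                                           noiseless_preprocessed):
        import copy
        epochs = [copy.copy(ep) for ep in noiseless_preprocessed[0]]
        ref = epochs[0].data
        for ep, flat in zip(epochs, range(1, 13)):
            ep.data = ref
        vec = p300.score_trial(noiseless_p300_model, epochs)
        assert np.allclose(vec, vec[0])

    def test_missing_line_rejected(self, noiseless_p300_model, noiseless_preprocessed):
        with pytest.raises(ValueError):
            p300.score_trial(noiseless_p300_model, noiseless_preprocessed[0][:11])
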