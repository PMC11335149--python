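"""Training loop contracts, accuracy evaluation, and the band-power baseline."""

import numpy as np
import pytest

from neurixn.data_model import CVSplit, WindowSample, make_within_splits
from neurixn.model import ModelConfig, build_model
from neurixn.training import (
    FeatureSample,
    bandpower_features,
    evaluate_accuracy,
    train_baseline,
    train_decoder,
    windows_to_features,
)

FS = 64.0


def _toy_windows(rng, n_trials=8, per_trial=4, T=128):
    """Separable toy set: class-0 trials carry a loud channel 3."""
    wins = []
    for t in range(n_trials):
        label = "left" if t % 2 == 0 else "right"
        for _ in range(per_trial):
            data = rng.normal(size=(30, T))
            if label == "left":
                data[3] *= 4.0
            wins.append(
                WindowSample(data=data, label=label, trial_id=t, block_id=t % 4)
            )
    return wins


def _split(scope="within"):
    return CVSplit(
        fold_id=0,
        train_ids=frozenset({0, 1, 2, 3}),
        val_ids=frozenset({4, 5}),
        test_ids=frozenset({6, 7}),
        scope=scope,
    )


class TestTrainDecoder:
    def test_same_seed_identical_val_curves(self, rng):
        wins = _toy_windows(rng)
        reports = []
        for _ in range(2):
            m = build_model(ModelConfig(), window_len=128, seed=0)
            reports.append(train_decoder(m, _split(), wins, epochs=3, seed=11))
        assert reports[0].val_loss_curve == reports[1].val_loss_curve
        assert reports[0].test_accuracy == reports[1].test_accuracy

    def test_best_epoch_is_argmin_of_curve(self, rng):
        wins = _toy_windows(rng)
        m = build_model(ModelConfig(), window_len=128, seed=1)
        rep = train_decoder(m, _split(), wins, epochs=4, seed=2)
        assert rep.best_epoch == int(np.argmin(rep.val_loss_curve))
        assert min(rep.val_loss_curve) <= rep.val_loss_curve[rep.best_epoch] + 1e-12

    def test_empty_partition_rejected(self, rng):
        wins = [w for w in _toy_windows(rng) if w.trial_id not in (4, 5)]
        m = build_model(ModelConfig(), window_len=128, seed=1)
        with pytest.raises(ValueError):
            train_decoder(m, _split(), wins, epochs=1, seed=0)

    def test_learns_separable_toy_data(self):
        # class-dependent global gain: every interaction channel is informative
        r = np.random.default_rng(100)
        wins = []
        for t in range(12):
            label = "left" if t % 2 == 0 else "right"
            for _ in range(6):
                data = r.normal(size=(30, 128))
                if label == "left":
                    data *= 2.5
                wins.append(
                    WindowSample(data=data, label=label, trial_id=t, block_id=t % 4)
                )
        split = CVSplit(
            fold_id=0,
            train_ids=frozenset(range(6)),
            val_ids=frozenset({6, 7, 8}),
            test_ids=frozenset({9, 10, 11}),
            scope="within",
        )
        m = build_model(ModelConfig(), window_len=128, seed=3)
        rep = train_decoder(m, split, wins, epochs=25, seed=3)
        assert rep.test_accuracy >= 0.8


class TestEvaluateAccuracy:
    def test_matches_manual_count(self, rng):
        m = build_model(ModelConfig(), window_len=128, seed=5)
        m.params["W6"] = rng.normal(0, 0.3, size=m.params["W6"].shape).astype(m.dtype)
        wins = _toy_windows(rng)
        acc = evaluate_accuracy(m, wins)
        X = np.stack([w.data for w in wins])
        y = np.array([0 if w.label == "left" else 1 for w in wins])
        manual = np.mean(np.argmax(m.forward(X), axis=1) == y)
        assert acc == pytest.approx(manual)

    def test_constant_predictor_on_balanced_set_is_half(self, rng):
        m = build_model(ModelConfig(), window_len=128, seed=5)
        m.params["W6"][:] = 0.0  # logits identical -> argmax always class 0
        wins = _toy_windows(rng)
        assert evaluate_accuracy(m, wins) == pytest.approx(0.5)

    def test_empty_set_rejected(self):
        m = build_model(ModelConfig(), window_len=128, seed=5)
        with pytest.raises(ValueError):
            evaluate_accuracy(m, [])


class TestBandpowerFeatures:
    def test_output_length_40(self, rng):
        feats = bandpower_features(rng.normal(size=(30, 320)), FS)
        assert feats.shape == (40,)

    def test_sinusoid_concentrates_in_alpha(self):
        t = np.arange(640) / FS
        data = np.zeros((30, 640))
        data[3:6] = np.sin(2 * np.pi * 10 * t)  # region LC? no: region index 1 = LP
        feats = bandpower_features(data, FS).reshape(10, 4)
        region = 1  # channels 3..5 belong to the second region (LP)
        assert feats[region, 2] > feats[region, 0]
        assert feats[region, 2] > feats[region, 1]
        assert feats[region, 2] > feats[region, 3]

    def test_zero_signal_hits_log_floor(self):
        feats = bandpower_features(np.zeros((30, 320)), FS)
        assert np.all(feats == feats[0])
        assert feats[0] == pytest.approx(-12.0, abs=0.5)

    def test_too_short_window_rejected(self, rng):
        with pytest.raises(ValueError):
            bandpower_features(rng.normal(size=(30, 32)), FS)


class TestTrainBaseline:
    SPLIT16 = CVSplit(
        fold_id=0,
        train_ids=frozenset(range(8)),
        val_ids=frozenset({8, 9, 10, 11}),
        test_ids=frozenset({12, 13, 14, 15}),
        scope="within",
    )

    def _samples(self, rng, n_trials=16, per=8, informative=True):
        out = []
        for t in range(n_trials):
            label = "left" if t % 2 == 0 else "right"
            for _ in range(per):
                f = rng.normal(size=40)
                if informative and label == "left":
                    f[26] += 3.0  # RP alpha feature
                out.append(FeatureSample(features=f, label=label, trial_id=t))
        return out

    def test_weight_vector_has_40_entries(self, rng):
        mdl, _ = train_baseline(self._samples(rng), self.SPLIT16, seed=0, n_iter=50)
        assert mdl.weights.shape == (40,)

    def test_learns_planted_feature(self, rng):
        mdl, rep = train_baseline(self._samples(rng), self.SPLIT16, seed=0, n_iter=800)
        assert rep.test_accuracy >= 0.7

    def test_uninformative_features_near_prior(self, rng):
        accs = []
        for seed in range(3):
            _, rep = train_baseline(
                self._samples(rng, informative=False), self.SPLIT16, seed=seed, n_iter=200
            )
            accs.append(rep.test_accuracy)
        assert 0.2 <= np.mean(accs) <= 0.8

    def test_full_pipeline_features_from_windows(self, tiny_trial_set):
        from neurixn.data_model import assign_blocks
        from neurixn.pipeline import windows_for_participant

        splits = make_within_splits(tiny_trial_set, seed=0)
        blocks = assign_blocks(
            tiny_trial_set.conditions, 4, 0, labels=tiny_trial_set.labels
        )
        wins = windows_for_participant(
            tiny_trial_set, splits[0].train_ids, blocks, window_seconds=2.0
        )
        feats = windows_to_features(wins)
        assert all(f.features.shape == (40,) for f in feats)
        mdl, rep = train_baseline(feats, splits[0], seed=0, n_iter=100)
        assert 0.0 <= rep.test_accuracy <= 1.0
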