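"""Metrics and evaluation protocols: confusion arithmetic against an
independent oracle, online latency rules, and protocol hygiene."""

import numpy as np
import pytest

from mrcp import evalproto
from mrcp.epochs import LabeledWindow
from mrcp.evalproto import OnlinePrediction


def brute_force_counts(y_true, y_pred):
    """Element-by-element confusion counting, independent of the module."""
    tp = fn = fp = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 1 and p == 0:
            fn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            tn += 1
    return tp, fn, fp, tn


class TestConfusionMetrics:
    def test_worked_example(self):
        # TP=9 FN=1 FP=2 TN=8
        y_true = [1] * 10 + [0] * 10
        y_pred = [1] * 9 + [0] + [1] * 2 + [0] * 8
        r = evalproto.confusion_metrics(y_true, y_pred)
        assert r.accuracy == pytest.approx(0.85)
        assert r.recall == pytest.approx(0.9)
        assert r.precision == pytest.approx(9 / 11)
        assert r.f1 == pytest.approx(2 * 0.9 * (9 / 11) / (0.9 + 9 / 11))

    def test_perfect_prediction(self):
        r = evalproto.confusion_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert r.accuracy == r.recall == r.precision == r.f1 == 1.0

    def test_all_negative_predictions_convention(self):
        with pytest.warns(UserWarning):
            r = evalproto.confusion_metrics([1, 1, 0], [0, 0, 0])
        assert r.recall == 0.0 and r.precision == 0.0 and r.f1 == 0.0

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 200))
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            if not np.any(y_true) or np.all(y_pred == 0):
                continue
            tp, fn, fp, tn = brute_force_counts(y_true, y_pred)
            r = evalproto.confusion_metrics(y_true, y_pred)
            assert (r.counts.TP, r.counts.FN, r.counts.FP, r.counts.TN) == (tp, fn, fp, tn)
            assert r.accuracy * r.counts.total == pytest.approx(tp + tn, abs=1e-9)
            if r.recall + r.precision > 0:
                assert r.f1 == pytest.approx(
                    2 * r.recall * r.precision / (r.recall + r.precision), abs=1e-12
                )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evalproto.confusion_metrics([], [])


class _TaggedModel:
    """Classifier that reads the decision from a tag the test writes into
    the first sample of each window (channel 0)."""

    def __call__(self, batch):
        tags = batch[:, 0, -1, 0] - batch[:, 0, 0, 0]
        p1 = (tags > 0).astype(float)
        return np.column_stack([1 - p1, p1])


def _recording_with_tag(fs, onset, fire_start_s, fire_stop_s, n=None):
    """EEG whose channel-0 slope is positive only where a stub model should
    fire: between fire_start_s and fire_stop_s relative to the onset."""
    if n is None:
        n = onset + int(2 * fs)
    eeg = np.zeros((2, n))
    t = (np.arange(n) - onset) / fs
    mask = (t >= fire_start_s) & (t <= fire_stop_s)
    eeg[0] = np.cumsum(mask.astype(float))  # positive slope inside the span
    return eeg


class TestOnlineSimulate:
    fs = 128.0

    def test_valid_prediction_before_onset(self):
        onset = int(6 * self.fs)
        eeg = _recording_with_tag(self.fs, onset, -0.9, 1.0)
        preds, info = evalproto.online_simulate(
            _TaggedModel(), eeg, [onset], self.fs, debounce_k=2
        )
        assert len(preds) == 1
        p = preds[0]
        assert p.valid and p.outcome == "valid"
        assert -1.0 < p.predict_time < 0.0
        assert info["rest_false_alarms"] == 0

    def test_post_onset_positive_marked_wrong(self):
        onset = int(6 * self.fs)
        eeg = _recording_with_tag(self.fs, onset, 0.1, 1.0)
        preds, _ = evalproto.online_simulate(
            _TaggedModel(), eeg, [onset], self.fs, debounce_k=1
        )
        assert preds[0].outcome == "wrong"
        assert preds[0].predict_time == 0.0
        assert not preds[0].valid

    def test_silent_model_is_miss(self):
        onset = int(6 * self.fs)
        eeg = np.zeros((2, onset + int(2 * self.fs)))
        preds, _ = evalproto.online_simulate(
            _TaggedModel(), eeg, [onset], self.fs
        )
        assert preds[0].outcome == "miss"

    def test_rest_period_false_alarm_counted_not_latched(self):
        onset = int(6 * self.fs)
        # fires only well before the prediction window
        eeg = _recording_with_tag(self.fs, onset, -2.5, -1.8)
        preds, info = evalproto.online_simulate(
            _TaggedModel(), eeg, [onset], self.fs, debounce_k=1
        )
        assert info["rest_false_alarms"] >= 1
        assert preds[0].outcome == "miss"

    def test_no_valid_prediction_has_nonnegative_latency(self):
        # soundness: valid <=> dt1 < 0, regardless of model behavior
        onset = int(6 * self.fs)
        for span in [(-0.9, 1.0), (0.0, 1.0), (-2.0, 2.0)]:
            eeg = _recording_with_tag(self.fs, onset, *span)
            preds, _ = evalproto.online_simulate(
                _TaggedModel(), eeg, [onset], self.fs, debounce_k=1
            )
            for p in preds:
                assert p.valid == (p.predict_time < 0)


class TestLatencyStats:
    def test_median_of_known_latencies(self):
        preds = [
            OnlinePrediction(0, -0.710, True),
            OnlinePrediction(1, -0.470, True),
            OnlinePrediction(2, -0.2725, True),
        ]
        s = evalproto.latency_stats(preds)
        assert s["median_ms"] == pytest.approx(-470.0)
        assert s["mean_ms"] == pytest.approx(np.mean([-710, -470, -272.5]))
        assert s["accuracy"] == 1.0

    def test_all_invalid(self):
        preds = [OnlinePrediction(0, 0.0, False, "wrong"),
                 OnlinePrediction(1, 0.0, False, "miss")]
        s = evalproto.latency_stats(preds)
        assert s["accuracy"] == 0.0
        assert "mean_ms" not in s

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evalproto.latency_stats([])


class TestProtocolHygiene:
    def test_cross_temporal_requires_single_session(self):
        wins = [LabeledWindow(np.zeros((2, 4)), "rest", 0.0, session_id=s)
                for s in (0, 1)]
        with pytest.raises(ValueError):
            evalproto.cross_temporal_eval(None, wins, use_tl=False, fs=128.0)

    def test_cross_subject_requires_cohort(self):
        wins = [LabeledWindow(np.zeros((2, 4)), "rest", 0.0, subject_id=0)]
        with pytest.raises(ValueError):
            evalproto.cross_subject_eval(wins, 0, use_tl=False, fs=128.0)


class TestCrossTemporalFunctional:
    def test_counts_and_tagging(self, rng):
        """A session-1 model evaluated on session 2 reports counts that sum
        to the session-2 test split, with and without transfer."""
        from mrcp import cnn_tl
        from mrcp.cnn_tl import TrainConfig, TransferConfig

        def windows(session_id, n_trials=6):
            out = []
            for t in range(n_trials):
                for k in range(4):
                    label = "intention" if k % 2 else "rest"
                    data = rng.standard_normal((8, 52))
                    if label == "intention":
                        data -= np.linspace(0, 8, 52)
                    out.append(LabeledWindow(data, label, 0.0, trial_id=t,
                                             session_id=session_id))
            return out

        s1, s2 = windows(0), windows(1)
        from mrcp.epochs import to_tensor
        X1, y1 = to_tensor(s1, 128.0)
        spec = cnn_tl.build_vgg(X1.shape[1:], 2, width_multiplier=0.125)
        model, _ = cnn_tl.train(spec, (X1, y1), TrainConfig(epochs=3, seed=0))

        for use_tl in (False, True):
            r = evalproto.cross_temporal_eval(
                model, s2, use_tl=use_tl, fs=128.0,
                train_cfg=TrainConfig(lr=1e-3, epochs=2, seed=1),
                transfer_cfg=TransferConfig(frozen_depth=8),
            )
            assert r.protocol == "cross_temporal"
            # 30% of 6 trials -> 2 trials -> 8 windows
            assert r.counts.total == 8
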