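"""Offline metrics, cross-temporal/cross-subject protocols, and the online
prediction simulation with latency accounting.

Offline performance is summarized by accuracy, recall, precision, and F1
computed from confusion counts. The online simulation slides a causal
400 ms window over a continuous recording; the first debounced
intention-positive decision per trial defines the prediction latency
dt1 = decision time - true onset. Only dt1 < 0 is a genuine prediction:
a first positive at or after the onset is a wrong prediction and its dt1
is recorded as 0; no positive at all is a miss. Positives earlier than
1 s before the onset fall outside the pre-onset prediction window and
are tallied separately as rest-period false alarms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from mrcp import cnn_tl, epochs as _epochs
from mrcp.cnn_tl import CNNModel, TrainConfig, TransferConfig
from mrcp.epochs import LabeledWindow, baseline_calibrate, split_train_test, to_tensor


@dataclass
class ConfusionCounts:
    TP: int
    FN: int
    FP: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN


@dataclass
class MetricReport:
    """Accuracy / recall / precision / F1 with their confusion counts."""

    counts: ConfusionCounts
    accuracy: float
    recall: float
    precision: float
    f1: float
    protocol: str = "within"


@dataclass
class OnlinePrediction:
    """Per-trial online outcome.

    ``predict_time`` is dt1 in seconds relative to the true onset
    (negative for a genuine prediction, 0 for wrong predictions and
    misses); ``valid`` is True iff dt1 < 0; outcome is one of
    "valid" / "wrong" / "miss".
    """

    trial_id: int
    predict_time: float
    valid: bool
    outcome: str = "valid"


def confusion_metrics(y_true, y_pred, protocol: str = "within") -> MetricReport:
    """Accuracy, recall, precision, F1 from binary labels and predictions.

    Positive class is 1 (movement intention). Precision and recall are
    defined as 0 with a warning when their denominator is empty.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal lengths")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    counts = ConfusionCounts(TP=tp, FN=fn, FP=fp, TN=tn)
    accuracy = (tp + tn) / counts.total

    if tp + fn == 0:
        warnings.warn("no positive ground-truth labels: recall defined as 0", stacklevel=2)
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    if tp + fp == 0:
        warnings.warn("no positive predictions: precision defined as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    f1 = 0.0 if recall + precision == 0 else 2 * recall * precision / (recall + precision)
    return MetricReport(counts=counts, accuracy=accuracy, recall=recall,
                        precision=precision, f1=f1, protocol=protocol)


def _predict_labels(model, X: np.ndarray) -> np.ndarray:
    proba = model(X) if callable(model) and not isinstance(model, CNNModel) \
        else cnn_tl.predict(model, X)
    return np.argmax(proba, axis=1)


def cross_temporal_eval(
    model: CNNModel,
    session2_windows: list[LabeledWindow],
    use_tl: bool,
    *,
    fs: float,
    train_cfg: TrainConfig | None = None,
    transfer_cfg: TransferConfig | None = None,
    train_frac: float = 0.7,
) -> MetricReport:
    """Evaluate a session-1 model on a later session of the same subject.

    With ``use_tl`` the pretrained model is transferred (head replaced,
    low layers frozen) and fine-tuned on the chronological train split of
    session 2, then tested on its test split; without, the session-1 model
    is applied to the same test split directly.
    """
    subjects = {w.subject_id for w in session2_windows}
    sessions = {w.session_id for w in session2_windows}
    if len(subjects) != 1 or len(sessions) != 1:
        raise ValueError(
            "cross-temporal evaluation requires windows from exactly one "
            f"session of one subject (got subjects={subjects}, sessions={sessions})"
        )
    train_w, test_w = split_train_test(session2_windows, train_frac)
    X_test, y_test = to_tensor(test_w, fs)
    if use_tl:
        target = cnn_tl.transfer(model, model.spec.n_classes, transfer_cfg)
        X_tr, y_tr = to_tensor(train_w, fs)
        cfg = train_cfg if train_cfg is not None else TrainConfig(lr=1e-4, epochs=10)
        cnn_tl.fine_tune(target, (X_tr, y_tr), cfg)
        y_pred = _predict_labels(target, X_test)
    else:
        y_pred = _predict_labels(model, X_test)
    return confusion_metrics(y_test, y_pred, protocol="cross_temporal")


def cross_subject_eval(
    cohort_windows: list[LabeledWindow],
    held_out_subject: int,
    use_tl: bool,
    *,
    fs: float,
    spec: cnn_tl.ModelSpec | None = None,
    pretrain_cfg: TrainConfig | None = None,
    finetune_cfg: TrainConfig | None = None,
    transfer_cfg: TransferConfig | None = None,
    train_frac: float = 0.7,
    pretrained: CNNModel | None = None,
) -> MetricReport:
    """Leave-one-subject-out evaluation.

    A network is pretrained on every other subject's windows (or supplied
    ready-made via ``pretrained``), then evaluated on the held-out
    subject's chronological test split — after transfer + fine-tuning on
    the held-out train split when ``use_tl``. No held-out window ever
    enters pretraining (audited by subject id).
    """
    subjects = sorted({w.subject_id for w in cohort_windows})
    if len(subjects) < 2:
        raise ValueError("cross-subject evaluation requires a cohort of >= 2 subjects")
    if held_out_subject not in subjects:
        raise ValueError(f"held-out subject {held_out_subject} not in cohort {subjects}")

    source_w = [w for w in cohort_windows if w.subject_id != held_out_subject]
    target_w = [w for w in cohort_windows if w.subject_id == held_out_subject]
    assert not any(w.subject_id == held_out_subject for w in source_w)

    if pretrained is None:
        X_src, y_src = to_tensor(source_w, fs)
        if spec is None:
            spec = cnn_tl.build_vgg(X_src.shape[1:], n_classes=2)
        cfg = pretrain_cfg if pretrain_cfg is not None else TrainConfig(epochs=10)
        pretrained, _ = cnn_tl.train(spec, (X_src, y_src), cfg)

    train_w, test_w = split_train_test(target_w, train_frac)
    X_test, y_test = to_tensor(test_w, fs)
    if use_tl:
        target = cnn_tl.transfer(pretrained, pretrained.spec.n_classes, transfer_cfg)
        X_tr, y_tr = to_tensor(train_w, fs)
        cfg = finetune_cfg if finetune_cfg is not None else TrainConfig(lr=1e-4, epochs=10)
        cnn_tl.fine_tune(target, (X_tr, y_tr), cfg)
        y_pred = _predict_labels(target, X_test)
    else:
        y_pred = _predict_labels(pretrained, X_test)
    return confusion_metrics(y_test, y_pred, protocol="cross_subject")


def online_simulate(
    model,
    eeg: np.ndarray,
    true_onsets: np.ndarray,
    fs: float,
    *,
    window_ms: float = 400.0,
    step_ms: float = 50.0,
    debounce_k: int = 2,
    scan_pre_s: float = 3.0,
    scan_post_s: float = 1.0,
    baseline_ms: float = 100.0,
) -> tuple[list[OnlinePrediction], dict]:
    """Causal sliding-window intention prediction over a continuous record.

    For each trial, windows ending between ``scan_pre_s`` before and
    ``scan_post_s`` after the true onset are scored in temporal order;
    ``debounce_k`` consecutive intention-positive windows latch one
    decision per trial at the last window's end time. dt1 = decision time
    - onset. Decisions earlier than 1 s before onset are rest-period
    false alarms, counted separately and not latched. ``model`` is a
    trained CNN or any callable mapping a (N, C, T, 1) batch to class
    probabilities.

    Returns (per-trial predictions, info) where info counts rest-period
    false alarms.
    """
    eeg = np.asarray(eeg, dtype=float)
    true_onsets = np.asarray(true_onsets, dtype=int)
    win = _epochs.window_samples(window_ms, fs)
    step = max(1, int(round(step_ms / 1000.0 * fs)))
    n = eeg.shape[1]
    predictions: list[OnlinePrediction] = []
    rest_alarms = 0

    for k, onset in enumerate(true_onsets):
        first_end = max(win, onset - int(round(scan_pre_s * fs)) + win)
        last_end = min(n, onset + int(round(scan_post_s * fs)))
        ends = list(range(first_end, last_end + 1, step))
        consec = 0
        outcome = None
        for end in ends:
            seg = eeg[:, end - win : end][None, :, :, None]
            seg = baseline_calibrate(seg, fs, baseline_ms)
            label = int(_predict_labels(model, seg)[0])
            if label != 1:
                consec = 0
                continue
            consec += 1
            if consec < debounce_k:
                continue
            dt1 = (end - onset) / fs
            if dt1 < -1.0:
                rest_alarms += 1
                consec = 0
                continue
            if dt1 < 0:
                predictions.append(OnlinePrediction(k, dt1, True, "valid"))
            else:
                predictions.append(OnlinePrediction(k, 0.0, False, "wrong"))
            outcome = "latched"
            break
        if outcome is None:
            predictions.append(OnlinePrediction(k, 0.0, False, "miss"))
    return predictions, {"rest_false_alarms": rest_alarms}


def latency_stats(predictions: list[OnlinePrediction]) -> dict:
    """Latency summary over valid trials and online accuracy over all trials.

    Latencies are reported in milliseconds (negative = before onset).
    """
    if not predictions:
        raise ValueError("need at least one prediction")
    valid = [p.predict_time * 1000.0 for p in predictions if p.valid]
    stats = {
        "n_trials": len(predictions),
        "n_valid": len(valid),
        "n_wrong": sum(p.outcome == "wrong" for p in predictions),
        "n_miss": sum(p.outcome == "miss" for p in predictions),
        "accuracy": len(valid) / len(predictions),
    }
    if valid:
        stats.update(
            mean_ms=float(np.mean(valid)),
            median_ms=float(np.median(valid)),
            min_ms=float(np.min(valid)),
            max_ms=float(np.max(valid)),
        )
    return stats
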