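"""High-level experiment helpers chaining the pipeline stages.

These wrap the common synthetic-cohort workflows: turning recordings into
labeled window sets, and the paired CNN+TL vs CNN vs SVM cross-subject
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mrcp import cnn_tl, epochs, evalproto, synthgen
from mrcp.cnn_tl import CNNModel, TrainConfig, TransferConfig
from mrcp.epochs import LabeledWindow


def session_windows(
    rec: synthgen.SessionRecording,
    *,
    band: tuple[float, float] = (0.05, 3.0),
    window_ms: float = 400.0,
    step_ms: float | None = None,
) -> list[LabeledWindow]:
    """Band-pass, align epochs on the ground-truth onsets, cut labeled windows."""
    eeg = epochs.bandpass_eeg(rec.eeg, rec.fs, band)
    eps = epochs.align_epochs(
        eeg, rec.true_onsets, rec.fs, legs=rec.leg_labels,
        subject_id=rec.subject_id, session_id=rec.session_id,
    )
    return [w for ep in eps for w in epochs.label_windows(ep, window_ms, step_ms)]


def cohort_windows(
    recordings: list[synthgen.SessionRecording], **kwargs
) -> list[LabeledWindow]:
    return [w for rec in recordings for w in session_windows(rec, **kwargs)]


@dataclass
class TLComparison:
    """Paired cross-subject results for one cohort seed."""

    acc_tl: float
    acc_cnn: float
    acc_svm: float
    epochs_to_target_ft: int
    epochs_to_target_scratch: int


def _epochs_to_reach(val_losses: list[float], target: float, cap: int) -> int:
    """1-based epoch index at which the loss first reaches ``target``."""
    for i, v in enumerate(val_losses):
        if v <= target + 1e-9:
            return i + 1
    return cap + 1


def tl_cross_subject_comparison(
    seed: int,
    *,
    n_subjects: int = 5,
    n_trials: int = 15,
    fs: float = 128.0,
    held_out: int = 0,
    width_multiplier: float = 0.25,
    pretrain_epochs: int = 15,
    adapt_epochs: int = 20,
    frozen_depth: int = 8,
    source_step_ms: float = 200.0,
    band: tuple[float, float] = (0.05, 12.0),
) -> TLComparison:
    """One paired cross-subject run: CNN+TL vs CNN vs SVM on a fresh cohort.

    A cohort of ``n_subjects`` single-session subjects is generated with
    between-subject variability; one subject is held out. The CNN is
    pretrained on the others and (a) applied directly to the held-out test
    split, (b) transferred and fine-tuned on the held-out train split
    first. The SVM-RBF baseline trains on the pooled source subjects. The
    epoch budgets to reach the scratch model's best validation loss are
    recorded for the fine-tuned and from-scratch models.

    Source-domain windows are cut with a half-window step (overlapping),
    the usual augmentation against trial-to-trial latency variation;
    held-out evaluation windows stay non-overlapping.
    """
    recs = synthgen.make_cohort(
        n_subjects=n_subjects, n_sessions=1, seed=seed, n_trials=n_trials, fs=fs
    )
    source_w = [w for rec in recs if rec.subject_id != held_out
                for w in session_windows(rec, band=band, step_ms=source_step_ms)]
    target_w = [w for rec in recs if rec.subject_id == held_out
                for w in session_windows(rec, band=band)]

    X_src, y_src = epochs.to_tensor(source_w, fs)
    train_w, test_w = epochs.split_train_test(target_w)
    X_tr, y_tr = epochs.to_tensor(train_w, fs)
    X_te, y_te = epochs.to_tensor(test_w, fs)

    spec = cnn_tl.build_vgg(X_src.shape[1:], n_classes=2,
                            width_multiplier=width_multiplier)
    pre_cfg = TrainConfig(epochs=pretrain_epochs, seed=seed)
    pretrained, _ = cnn_tl.train(spec, (X_src, y_src), pre_cfg)

    # (a) direct cross-subject CNN
    acc_cnn = float(np.mean(
        np.argmax(cnn_tl.predict(pretrained, X_te), axis=1) == y_te))

    # (b) transfer + fine-tune on the held-out train split
    target = cnn_tl.transfer(pretrained, 2,
                             TransferConfig(frozen_depth=frozen_depth, seed=seed))
    ft_cfg = TrainConfig(lr=3e-4, epochs=adapt_epochs, batch_size=16,
                         seed=seed, patience=adapt_epochs)
    _, ft_hist = cnn_tl.fine_tune(target, (X_tr, y_tr), ft_cfg, val=(X_te, y_te))
    acc_tl = float(np.mean(
        np.argmax(cnn_tl.predict(target, X_te), axis=1) == y_te))

    # scratch model on the held-out train split (epoch-budget comparison)
    sc_cfg = TrainConfig(lr=1e-3, epochs=adapt_epochs, seed=seed, patience=adapt_epochs)
    _, sc_hist = cnn_tl.train(spec, (X_tr, y_tr), sc_cfg, val=(X_te, y_te))
    scratch_best = min(sc_hist["val_loss"])
    ep_ft = _epochs_to_reach(ft_hist["val_loss"], scratch_best, adapt_epochs)
    ep_sc = _epochs_to_reach(sc_hist["val_loss"], scratch_best, adapt_epochs)

    # SVM-RBF baseline trained on the pooled source subjects
    y_svm = cnn_tl.svm_baseline((X_src, y_src), X_te)
    acc_svm = float(np.mean(y_svm == y_te))

    return TLComparison(acc_tl=acc_tl, acc_cnn=acc_cnn, acc_svm=acc_svm,
                        epochs_to_target_ft=ep_ft, epochs_to_target_scratch=ep_sc)


def online_prediction_demo(
    seed: int,
    *,
    n_train_trials: int = 10,
    n_test_trials: int = 8,
    fs: float = 128.0,
    eeg_noise_sd: float = 6.0,
    train_epochs: int = 12,
    band: tuple[float, float] = (0.05, 3.0),
    debounce_k: int = 2,
) -> tuple[list, dict, dict]:
    """Train on one low-noise session and run the online simulation on a
    second session of the same synthetic subject.

    The low noise level makes the classifier near-ceiling so the run
    exercises the latency accounting (dt1 in [-1000, 0) ms for valid
    predictions) rather than classifier quality. Returns
    (per-trial predictions, latency stats, simulation info).
    """
    profile_train = synthgen.SubjectProfile(eeg_noise_sd=eeg_noise_sd, seed=seed)
    profile_test = synthgen.SubjectProfile(eeg_noise_sd=eeg_noise_sd, seed=seed + 1)
    rec_train = synthgen.make_session(profile=profile_train,
                                      n_trials=n_train_trials, fs=fs)
    rec_test = synthgen.make_session(profile=profile_test,
                                     n_trials=n_test_trials, fs=fs)

    train_w = session_windows(rec_train, band=band, step_ms=200.0)
    X, y = epochs.to_tensor(train_w, fs)
    spec = cnn_tl.build_vgg(X.shape[1:], n_classes=2)
    model, _ = cnn_tl.train(spec, (X, y), TrainConfig(epochs=train_epochs, seed=seed))

    eeg = epochs.bandpass_eeg(rec_test.eeg, fs, band)
    preds, info = evalproto.online_simulate(
        model, eeg, rec_test.true_onsets, fs, debounce_k=debounce_k
    )
    return preds, evalproto.latency_stats(preds), info
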