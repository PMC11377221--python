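"""Onset-locked epoching, stage labeling, windowing, and train/test split.

Each movement onset defines an epoch spanning [-3.0, +1.0) s around it
(4096 samples at 1024 Hz, onset at the 3 s mark). Within an epoch,
[-3.0, -1.0) s is the resting stage and [-1.0, +1.0) s the movement-
intention stage; fixed-length windows (400 ms by default) fully inside a
stage inherit its label, and windows straddling the -1.0 s boundary are
discarded, so no window mixes stages.

Sample indices are 0-based and intervals half-open [start, end).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

PRE_S = 3.0          # seconds of epoch before onset
POST_S = 1.0         # seconds of epoch after onset
REST_STAGE = (-3.0, -1.0)       # seconds relative to onset
INTENTION_STAGE = (-1.0, 1.0)


@dataclass
class Epoch:
    """One onset-locked EEG slab: channels x samples, onset at t0_idx."""

    data: np.ndarray
    t0_idx: int
    fs: float
    trial_id: int = 0
    leg: str = "right"
    subject_id: int = 0
    session_id: int = 0


@dataclass
class LabeledWindow:
    """A channels x samples window with its stage label.

    ``t_start`` is the window start in seconds relative to the movement
    onset; label is "rest" or "intention".
    """

    data: np.ndarray
    label: str
    t_start: float
    trial_id: int = 0
    leg: str = "right"
    subject_id: int = 0
    session_id: int = 0


def window_samples(window_ms: float, fs: float) -> int:
    """Window length in samples: ceil keeps the window >= window_ms."""
    return int(np.ceil(window_ms / 1000.0 * fs))


def bandpass_eeg(
    eeg: np.ndarray, fs: float, band: tuple[float, float] = (0.05, 3.0)
) -> np.ndarray:
    """Zero-phase band-pass for the low-frequency RP content.

    Applied to the continuous recording (not per window: a 0.05 Hz edge is
    ill-conditioned on sub-second segments).
    """
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, eeg, axis=-1)


def align_epochs(
    eeg: np.ndarray,
    onsets: np.ndarray,
    fs: float,
    *,
    legs: list[str] | None = None,
    subject_id: int = 0,
    session_id: int = 0,
) -> list[Epoch]:
    """Cut one [-3, +1) s epoch per onset; edge-clipped onsets are skipped."""
    eeg = np.asarray(eeg, dtype=float)
    onsets = np.asarray(onsets, dtype=int)
    pre = int(round(PRE_S * fs))
    post = int(round(POST_S * fs))
    n = eeg.shape[1]
    epochs: list[Epoch] = []
    skipped = 0
    for k, onset in enumerate(onsets):
        if onset - pre < 0 or onset + post > n:
            skipped += 1
            continue
        epochs.append(
            Epoch(
                data=eeg[:, onset - pre : onset + post].copy(),
                t0_idx=pre,
                fs=fs,
                trial_id=k,
                leg=legs[k] if legs is not None else "right",
                subject_id=subject_id,
                session_id=session_id,
            )
        )
    if skipped:
        logger.info("align_epochs: skipped %d onset(s) too close to record edges", skipped)
    if not epochs:
        warnings.warn("no eligible onsets: returning empty epoch list", stacklevel=2)
    return epochs


def label_windows(
    epoch: Epoch,
    window_ms: float = 400.0,
    step_ms: float | None = None,
) -> list[LabeledWindow]:
    """Cut labeled windows from the rest and intention stages of one epoch.

    Default step equals the window length (non-overlapping). Windows are
    tiled from each stage start; the final tile is right-aligned to the
    stage end when ceil-rounding of the window length would overrun it, so
    a 2 s stage yields floor(2000 / window_ms) windows. Windows that would
    straddle the stage boundary are never produced.
    """
    fs = epoch.fs
    win = window_samples(window_ms, fs)
    step = win if step_ms is None else max(1, int(round(step_ms / 1000.0 * fs)))
    out: list[LabeledWindow] = []
    for (lo_s, hi_s), label in ((REST_STAGE, "rest"), (INTENTION_STAGE, "intention")):
        lo = epoch.t0_idx + int(round(lo_s * fs))
        hi = epoch.t0_idx + int(round(hi_s * fs))
        stage_len = hi - lo
        if win > stage_len:
            continue
        if step == win:
            n_win = int((hi_s - lo_s) * 1000.0 // window_ms)
            starts = [i * win for i in range(n_win)]
            if starts and starts[-1] + win > stage_len:
                starts[-1] = stage_len - win
        else:
            starts = list(range(0, stage_len - win + 1, step))
        for s in starts:
            out.append(
                LabeledWindow(
                    data=epoch.data[:, lo + s : lo + s + win].copy(),
                    label=label,
                    t_start=lo_s + s / fs,
                    trial_id=epoch.trial_id,
                    leg=epoch.leg,
                    subject_id=epoch.subject_id,
                    session_id=epoch.session_id,
                )
            )
    return out


def split_train_test(
    windows: list[LabeledWindow], train_frac: float = 0.7
) -> tuple[list[LabeledWindow], list[LabeledWindow]]:
    """Chronological 70/30 split, blocked by trial.

    The window list must be ordered by acquisition time; the split point is
    placed at the train_frac boundary of the *trial* sequence so that no
    trial contributes windows to both sides.
    """
    if not 0 < train_frac <= 1:
        raise ValueError("train_frac must be in (0, 1]")
    keys = []
    for w in windows:
        key = (w.subject_id, w.session_id, w.trial_id)
        if key not in keys:
            keys.append(key)
    if len(keys) < 2:
        raise ValueError("need at least 2 trials to split")
    n_train = int(round(len(keys) * train_frac))
    n_train = min(max(n_train, 1), len(keys))
    train_keys = set(keys[:n_train])
    train = [w for w in windows if (w.subject_id, w.session_id, w.trial_id) in train_keys]
    test = [w for w in windows if (w.subject_id, w.session_id, w.trial_id) not in train_keys]
    if not test:
        warnings.warn("train_frac leaves an empty test set", stacklevel=2)
    return train, test


def baseline_calibrate(batch: np.ndarray, fs: float, baseline_ms: float = 100.0) -> np.ndarray:
    """Subtract each channel's mean over the window's first ``baseline_ms``."""
    n_base = max(1, int(round(baseline_ms / 1000.0 * fs)))
    base = batch[..., :n_base, :].mean(axis=-2, keepdims=True)
    return batch - base


def to_tensor(
    windows: list[LabeledWindow],
    fs: float | None = None,
    *,
    band: tuple[float, float] | None = None,
    baseline_ms: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into a (count, channels, datapoints, 1) model batch.

    Per-window baseline calibration subtracts each channel's mean over the
    first ``baseline_ms``; an optional band-pass is applied first. Labels
    are 1 for intention, 0 for rest.
    """
    if not windows:
        return np.zeros((0, 0, 0, 1)), np.zeros(0, dtype=int)
    shapes = {w.data.shape for w in windows}
    if len(shapes) > 1:
        raise ValueError(f"heterogeneous window shapes: {sorted(shapes)}")
    if fs is None:
        fs = 1024.0
    X = np.stack([w.data for w in windows]).astype(np.float64)
    if band is not None:
        sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
        X = signal.sosfiltfilt(sos, X, axis=-1)
    X = X[..., None]  # (N, C, T, 1)
    X = baseline_calibrate(X, fs, baseline_ms)
    y = np.array([1 if w.label == "intention" else 0 for w in windows], dtype=int)
    return X, y
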