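"""EMG movement-onset trigger detection.

Pipeline: band-pass (20-200 Hz, 4th-order Butterworth, zero-phase) plus
powerline notch -> Hilbert envelope -> smoothing + mean removal + min-max
normalization to [-1, 1] -> adaptive-threshold binary state function S(n)
-> two-step state filtering (fill sub-TA rest gaps inside activity, then
zero sub-TN activity runs) -> rising edges of S(n) are the onset triggers.

The onset trigger is the zero time for EEG epoching, so all filtering is
zero-phase (forward-backward) to avoid group delay shifting the detected
onsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass
class OnsetConfig:
    """Detector parameters.

    alpha scales the initial threshold th_i = alpha * mean(E); beta blends
    the sliding-window mean toward the global mean in the threshold update
    th = win_mean + beta * (global_mean - win_mean). m and l are the
    smoothing-window and sliding-window lengths in samples (about 0.05 * fs
    when left as None). TA and TN are the state-filter spans in samples:
    rest gaps shorter than TA inside activity are filled, activity runs
    shorter than TN are zeroed.
    """

    fs: float = 1024.0
    alpha: float = 1.0
    beta: float = 0.5
    m: int | None = None
    l: int | None = None
    TA: int = 500
    TN: int = 1500
    band: tuple[float, float] = (20.0, 200.0)
    notch: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 10:
            raise ValueError(f"alpha must be in (0, 10], got {self.alpha}")
        if not 0 < self.beta <= 1:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if self.m is None:
            self.m = max(1, int(round(0.05 * self.fs)))
        if self.l is None:
            self.l = max(1, int(round(0.05 * self.fs)))
        for name in ("m", "l", "TA", "TN"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class EnvelopeSignal:
    """Smoothed, mean-removed, min-max-normalized envelope in [-1, 1]."""

    values: np.ndarray
    fs: float


@dataclass
class StateSequence:
    """Binary movement-state function S(n) and its 0->1 rising edges."""

    states: np.ndarray
    onsets: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.onsets is None:
            self.onsets = rising_edges(self.states)


def rising_edges(states: np.ndarray, include_start: bool = False) -> np.ndarray:
    """Indices where a binary sequence transitions 0 -> 1."""
    states = np.asarray(states)
    edges = np.flatnonzero(np.diff(states.astype(np.int8)) == 1) + 1
    if include_start and len(states) and states[0] == 1:
        edges = np.concatenate([[0], edges])
    return edges


def bandpass_emg(x: np.ndarray, cfg: OnsetConfig | None = None) -> np.ndarray:
    """20-200 Hz 4th-order Butterworth band-pass + powerline notch, zero-phase."""
    if cfg is None:
        cfg = OnsetConfig()
    x = np.asarray(x, dtype=float)
    if cfg.fs <= 2 * cfg.band[1]:
        raise ValueError(
            f"sampling rate {cfg.fs} Hz too low for a {cfg.band[1]} Hz passband edge"
        )
    sos = signal.butter(4, cfg.band, btype="bandpass", fs=cfg.fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    if cfg.notch:
        b, a = signal.iirnotch(cfg.notch, Q=30.0, fs=cfg.fs)
        y = signal.filtfilt(b, a, y)
    return y


def hilbert_kernel(n) -> np.ndarray | float:
    """Discrete Hilbert-transform kernel: 2/(n*pi) for odd n, 0 for even n."""
    n_arr = np.asarray(n)
    with np.errstate(divide="ignore"):
        vals = np.where(n_arr % 2 == 1, 2.0 / (np.pi * np.where(n_arr == 0, 1, n_arr)), 0.0)
    vals = np.where(n_arr == 0, 0.0, vals)
    if np.isscalar(n):
        return float(vals)
    return vals


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Non-negative envelope H(n) of the filtered EMG.

    Computed as the magnitude of the analytic signal x + i*HT(x), where HT
    is the Hilbert transform realized by the discrete kernel exposed in
    :func:`hilbert_kernel` (evaluated spectrally via scipy). For a pure
    tone of amplitude A the envelope is A away from the record edges.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return np.abs(signal.hilbert(x))


def smooth_normalize(H: np.ndarray, cfg: OnsetConfig | None = None) -> EnvelopeSignal:
    """Smooth the envelope, remove its mean, min-max rescale to [-1, 1].

    The smoothing window is a Hamming window of length m (about 0.05 * fs)
    normalized to unit sum; the input is edge-replicated before the
    same-length convolution so the smoothed envelope does not droop at the
    record boundaries.
    """
    if cfg is None:
        cfg = OnsetConfig()
    H = np.asarray(H, dtype=float)
    if len(H) <= cfg.m:
        raise ValueError(f"input length {len(H)} must exceed smoothing window m={cfg.m}")
    W = np.hamming(cfg.m)
    W /= W.sum()
    padded = np.pad(H, (cfg.m // 2, cfg.m - 1 - cfg.m // 2), mode="edge")
    ET = np.convolve(padded, W, mode="valid")
    ET = ET - ET.mean()
    lo, hi = ET.min(), ET.max()
    if hi == lo:
        raise ValueError("degenerate constant envelope: cannot normalize")
    E = 2.0 * (ET - lo) / (hi - lo) - 1.0
    return EnvelopeSignal(values=E, fs=cfg.fs)


def binary_state(E: EnvelopeSignal, cfg: OnsetConfig | None = None) -> StateSequence:
    """Adaptive-threshold state function: S(n) = 1 iff E(n) >= th.

    The initial threshold is th_i = alpha * mean(E). The threshold is then
    updated over non-overlapping sliding windows of length l and applied
    causally: the threshold computed from window j classifies window j+1,
    as th = win_mean + beta * (global_mean - win_mean).
    """
    if cfg is None:
        cfg = OnsetConfig(fs=E.fs)
    vals = E.values
    n = len(vals)
    global_mean = vals.mean()
    th = cfg.alpha * global_mean
    S = np.zeros(n, dtype=np.int8)
    for start in range(0, n, cfg.l):
        win = vals[start : start + cfg.l]
        S[start : start + cfg.l] = win >= th
        win_mean = win.mean()
        th = win_mean + cfg.beta * (global_mean - win_mean)
    return StateSequence(states=S)


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode: list of (value, start, length)."""
    out = []
    n = len(states)
    i = 0
    while i < n:
        j = i
        while j < n and states[j] == states[i]:
            j += 1
        out.append((int(states[i]), i, j - i))
        i = j
    return out


def filter_states(S: StateSequence, cfg: OnsetConfig | None = None) -> StateSequence:
    """Two-step pseudo-activity removal; idempotent.

    Step 1 fills rest (0) runs shorter than TA that lie strictly between
    two activity runs (momentary drops inside a contraction). Step 2,
    applied to the result, zeroes activity (1) runs shorter than TN
    (noise spikes during rest); boundary activity runs touching the record
    edges are also zeroed by TN, but boundary rest runs are never filled.
    """
    if cfg is None:
        cfg = OnsetConfig()
    states = np.asarray(S.states, dtype=np.int8).copy()
    n = len(states)

    # step 1: fill short 0-gaps strictly between 1-runs
    for value, start, length in _runs(states):
        if value == 0 and length < cfg.TA and start > 0 and start + length < n:
            states[start : start + length] = 1

    # step 2: zero short 1-runs (boundary runs included)
    for value, start, length in _runs(states):
        if value == 1 and length < cfg.TN:
            states[start : start + length] = 0

    return StateSequence(states=states)


def detect_onsets(S: StateSequence, *, edge_onsets: bool = False) -> np.ndarray:
    """Movement-onset triggers: the 0->1 rising edges of the filtered S(n).

    A sequence that starts in state 1 contributes an onset at index 0 only
    when ``edge_onsets`` is set (off by default: activity already underway
    at record start has no observable onset).
    """
    return rising_edges(S.states, include_start=edge_onsets)


def detect_emg_onsets(
    x: np.ndarray, cfg: OnsetConfig | None = None, *, edge_onsets: bool = False
) -> tuple[np.ndarray, StateSequence]:
    """Full detector: raw EMG trace -> (onset sample indices, filtered states)."""
    if cfg is None:
        cfg = OnsetConfig()
    filtered = bandpass_emg(x, cfg)
    H = hilbert_envelope(filtered)
    E = smooth_normalize(H, cfg)
    S = binary_state(E, cfg)
    S = filter_states(S, cfg)
    return detect_onsets(S, edge_onsets=edge_onsets), S
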