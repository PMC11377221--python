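"""Multivariate empirical-mode decomposition (MEMD) and EEG artifact removal.

MEMD decomposes an n-channel signal into multivariate intrinsic-mode
functions (IMFs) that share one index set across channels, avoiding the
mode misalignment of channel-wise EMD. Projection directions on the
(n-1)-sphere come from a low-discrepancy Hammersley point set; for each
direction the signal is projected, the projection's local maxima are
located, and a channel-wise cubic spline through the signal values at
those times forms one directional envelope. The mean over all K envelopes
is the local multivariate mean m(t); sifting iterates h <- h - m(h) until
a standard-deviation criterion holds.

Motion artifacts in EEG live below ~2 Hz; cleaning discards IMFs whose
dominant (FFT-peak) frequency falls below a 0.5 Hz cutoff and reconstructs
the rest. The residual trend is retained by default (the literal
reconstruction rule); pass ``drop_residual=True`` to remove it as well,
which is what actually eliminates slow drift that sifts into the residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import norm

_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53)


class SiftTermination(Exception):
    """Raised internally when too few extrema remain to continue sifting."""


@dataclass
class DirectionSet:
    """K unit vectors quasi-uniformly covering the (n-1)-sphere."""

    vectors: np.ndarray  # (K, n_dim)

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("direction vectors must be unit norm")

    def __len__(self) -> int:
        return len(self.vectors)


@dataclass
class SiftCriteria:
    """Sifting stop rule: SD between successive sifts below ``sd_threshold``
    (global normalized squared difference), with a hard cap of ``max_sifts``."""

    sd_threshold: float = 0.075
    max_sifts: int = 30


@dataclass
class IMFSet:
    """q multivariate IMFs plus the residual; summing reproduces the input."""

    imfs: np.ndarray      # (q, n_channels, T)
    residual: np.ndarray  # (n_channels, T)
    converged: bool = True

    @property
    def q(self) -> int:
        return self.imfs.shape[0]

    def reconstruct(self, keep: np.ndarray | None = None) -> np.ndarray:
        """Sum of (selected) IMFs plus the residual.

        ``keep`` may be a boolean mask of shape (q,) applied to every
        channel, or (q, n_channels) for per-channel selection.
        """
        if self.q == 0:
            return self.residual.copy()
        if keep is None:
            return self.imfs.sum(axis=0) + self.residual
        keep = np.asarray(keep, dtype=bool)
        if keep.ndim == 1:
            return self.imfs[keep].sum(axis=0) + self.residual
        return (self.imfs * keep[:, :, None]).sum(axis=0) + self.residual


def _van_der_corput(i: np.ndarray, base: int) -> np.ndarray:
    """Radical-inverse sequence in base ``base`` for integer indices i >= 1."""
    out = np.zeros(len(i), dtype=float)
    denom = np.ones(len(i), dtype=float)
    k = i.astype(np.int64).copy()
    while np.any(k > 0):
        denom *= base
        out += (k % base) / denom
        k //= base
    return out


def hammersley_directions(K: int, n_dim: int, seed: int | None = None) -> DirectionSet:
    """K quasi-uniform unit vectors on the (n_dim - 1)-sphere.

    For n_dim = 2 the Hammersley set is the 1-D lattice i/K mapped to
    uniformly spaced angles. For higher dimensions, a Hammersley point set
    in the unit cube (lattice first coordinate, van der Corput radical
    inverses in successive prime bases) is pushed onto the sphere through
    the inverse-Gaussian map, which preserves low discrepancy; the set is
    made antithetic (each direction paired with its negative) so envelope
    means of symmetric signals are unbiased. ``seed`` optionally applies
    one random rotation to the whole set; the result is deterministic in
    (K, n_dim, seed).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_dim < 2:
        raise ValueError("n_dim must be >= 2")
    if n_dim == 2:
        theta = 2.0 * np.pi * np.arange(K) / K
        vecs = np.column_stack([np.cos(theta), np.sin(theta)])
    else:
        if n_dim - 1 > len(_PRIMES):
            raise ValueError(f"n_dim {n_dim} exceeds supported dimensionality")
        half = (K + 1) // 2
        i = np.arange(1, half + 1)
        cube = np.empty((half, n_dim))
        cube[:, 0] = (i - 0.5) / half
        for d in range(1, n_dim):
            cube[:, d] = _van_der_corput(i, _PRIMES[d - 1])
        z = norm.ppf(np.clip(cube, 1e-12, 1 - 1e-12))
        vecs = z / np.linalg.norm(z, axis=1, keepdims=True)
        vecs = np.concatenate([vecs, -vecs])[:K]
    if seed is not None:
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((n_dim, n_dim))
        Q, R = np.linalg.qr(A)
        Q *= np.sign(np.diag(R))
        vecs = vecs @ Q.T
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    return DirectionSet(vectors=vecs)


def project(v: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Pointwise inner product of an (n, T) signal with one direction."""
    v = np.asarray(v, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if v.shape[0] != direction.shape[0]:
        raise ValueError(f"dimension mismatch: signal has {v.shape[0]} channels, "
                         f"direction has {direction.shape[0]}")
    return direction @ v


def _local_maxima(p: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of a 1-D sequence."""
    if len(p) < 3:
        return np.array([], dtype=int)
    return np.flatnonzero((p[1:-1] > p[:-2]) & (p[1:-1] >= p[2:])) + 1


def _mirrored_knots(t_ext: np.ndarray, y_ext: np.ndarray, T: int) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to 2 extrema about each record end to curb spline end swings."""
    ts = [t_ext]
    ys = [y_ext]
    n_mirror = min(2, len(t_ext))
    left_t = 2 * 0 - t_ext[:n_mirror][::-1]  # reflect about t=0
    left_y = y_ext[:, :n_mirror][:, ::-1]
    right_t = 2 * (T - 1) - t_ext[-n_mirror:][::-1]
    right_y = y_ext[:, -n_mirror:][:, ::-1]
    keep_l = left_t < t_ext[0]
    keep_r = right_t > t_ext[-1]
    t_all = np.concatenate([left_t[keep_l], t_ext, right_t[keep_r]])
    y_all = np.concatenate([left_y[:, keep_l], y_ext, right_y[:, keep_r]], axis=1)
    return t_all, y_all


def envelope_mean(v: np.ndarray, dirs: DirectionSet, min_extrema: int = 3) -> np.ndarray:
    """Multivariate mean m(t): average of the K directional envelopes.

    For each direction, the projection's local maxima define interpolation
    times; a natural cubic spline per channel through the signal values at
    those times (with 2 mirrored boundary knots per end) is one envelope.
    Raises :class:`SiftTermination` when fewer than half the directions
    have ``min_extrema`` usable maxima.
    """
    v = np.asarray(v, dtype=float)
    n_ch, T = v.shape
    t = np.arange(T)
    acc = np.zeros_like(v)
    used = 0
    for direction in dirs.vectors:
        p = direction @ v
        idx = _local_maxima(p)
        if len(idx) < min_extrema:
            continue
        t_all, y_all = _mirrored_knots(idx.astype(float), v[:, idx], T)
        spline = CubicSpline(t_all, y_all, axis=1, bc_type="natural")
        acc += spline(t)
        used += 1
    if used < max(1, len(dirs) // 2):
        raise SiftTermination(
            f"only {used}/{len(dirs)} directions have >= {min_extrema} extrema"
        )
    return acc / used


def sift_imf(
    v: np.ndarray,
    dirs: DirectionSet,
    criteria: SiftCriteria | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Extract one multivariate IMF: iterate h <- h - m(h) until SD is small.

    Returns (imf, remainder, converged). Non-convergence at the sift cap
    returns the current h with ``converged=False`` and a warning.
    """
    if criteria is None:
        criteria = SiftCriteria()
    v = np.asarray(v, dtype=float)
    h = v.copy()
    converged = False
    for _ in range(criteria.max_sifts):
        try:
            m = envelope_mean(h, dirs)
        except SiftTermination:
            converged = True
            break
        h_new = h - m
        denom = float(np.sum(h * h))
        sd = float(np.sum(m * m)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < criteria.sd_threshold:
            converged = True
            break
    if not converged:
        warnings.warn("sifting hit the iteration cap without meeting the SD criterion",
                      RuntimeWarning, stacklevel=2)
    return h, v - h, converged


def _enough_extrema(v: np.ndarray, dirs: DirectionSet, min_extrema: int = 3) -> bool:
    """True when at least half the projections still carry oscillations."""
    ok = 0
    for direction in dirs.vectors:
        if len(_local_maxima(direction @ v)) >= min_extrema:
            ok += 1
    return ok >= max(1, len(dirs) // 2)


def memd_decompose(
    v: np.ndarray,
    K: int = 64,
    max_imfs: int = 16,
    criteria: SiftCriteria | None = None,
    seed: int | None = None,
) -> IMFSet:
    """Full MEMD: repeated sifting on successive remainders.

    Stops when the remainder is extrema-poor (near-monotone trend) or
    ``max_imfs`` is reached. All channels share one IMF index set by
    construction, and sum(IMFs) + residual telescopes back to the input
    exactly.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 2:
        raise ValueError("input must be (n_channels, T)")
    n_ch, T = v.shape
    if T < 8:
        raise ValueError(f"record too short for extrema detection (T={T})")
    dirs = hammersley_directions(K, n_ch, seed=seed)
    residual = v.copy()
    imfs: list[np.ndarray] = []
    all_conv = True
    while len(imfs) < max_imfs and _enough_extrema(residual, dirs):
        h, residual, conv = sift_imf(residual, dirs, criteria)
        all_conv &= conv
        if not np.any(h):
            break
        imfs.append(h)
    stack = np.array(imfs) if imfs else np.empty((0, n_ch, T))
    return IMFSet(imfs=stack, residual=residual, converged=all_conv)


def dominant_frequency(imf: np.ndarray, fs: float) -> float:
    """Frequency (Hz) of the maximum-magnitude FFT bin, DC excluded."""
    imf = np.asarray(imf, dtype=float)
    if imf.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.any(imf):
        return 0.0
    spec = np.abs(np.fft.rfft(imf))
    freqs = np.fft.rfftfreq(len(imf), d=1.0 / fs)
    spec[0] = 0.0
    return float(freqs[np.argmax(spec)])


def remove_artifacts(
    eeg: np.ndarray,
    fs: float,
    cutoff: float = 0.5,
    *,
    K: int = 64,
    max_imfs: int = 16,
    criteria: SiftCriteria | None = None,
    drop_residual: bool = False,
    seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Remove sub-``cutoff`` Hz motion artifacts from multichannel EEG.

    Decomposes with MEMD, Fourier-transforms each IMF channel to find its
    dominant frequency, discards per channel the IMFs whose dominant
    frequency is below ``cutoff``, and reconstructs from the remaining
    components plus the residual trend (dropped instead when
    ``drop_residual`` is set). Returns (cleaned, info) where info carries
    the per-channel discard mask and dominant frequencies.

    A decomposition failure passes the input through unchanged with
    ``info["passthrough"] = True`` and a warning.
    """
    eeg = np.asarray(eeg, dtype=float)
    if not np.all(np.isfinite(eeg)):
        raise ValueError("EEG must be finite")
    try:
        dec = memd_decompose(eeg, K=K, max_imfs=max_imfs, criteria=criteria, seed=seed)
    except Exception as exc:  # decomposition failure -> pass-through
        warnings.warn(f"MEMD failed ({exc}); passing input through unchanged",
                      RuntimeWarning, stacklevel=2)
        return eeg.copy(), {"passthrough": True}

    n_ch = eeg.shape[0]
    dom = np.zeros((dec.q, n_ch))
    for i in range(dec.q):
        for c in range(n_ch):
            dom[i, c] = dominant_frequency(dec.imfs[i, c], fs)
    keep = dom >= cutoff
    cleaned = dec.reconstruct(keep=keep)
    if drop_residual:
        cleaned = cleaned - dec.residual
    info = {
        "passthrough": False,
        "q": dec.q,
        "dominant_frequencies": dom,
        "keep_mask": keep,
        "converged": dec.converged,
    }
    return cleaned, info
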