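"""EMG onset detector: filter responses, envelope, adaptive threshold,
state filtering rules, and ground-truth latency recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

from mrcp import emg_onset, synthgen
from mrcp.emg_onset import OnsetConfig, StateSequence


@pytest.fixture(scope="module")
def cfg1024():
    return OnsetConfig(fs=1024.0)


class TestBandpass:
    def test_passband_gain_near_unity(self, cfg1024):
        sos = signal.butter(4, cfg1024.band, btype="bandpass", fs=cfg1024.fs,
                            output="sos")
        w, h = signal.sosfreqz(sos, worN=[100.0], fs=cfg1024.fs)
        # zero-phase application squares the magnitude response
        assert abs(abs(h[0]) ** 2 - 1.0) < 0.05

    def test_stopband_attenuation(self, cfg1024):
        t = np.arange(int(4 * cfg1024.fs)) / cfg1024.fs
        x = np.sin(2 * np.pi * 5.0 * t)
        y = emg_onset.bandpass_emg(x, cfg1024)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        atten_db = 20 * np.log10(np.abs(y[mid]).max() / 1.0)
        assert atten_db <= -20.0

    def test_dc_removed(self, cfg1024):
        y = emg_onset.bandpass_emg(np.full(4096, 3.0), cfg1024)
        assert np.abs(y).max() < 1e-6

    def test_low_sampling_rate_rejected(self):
        cfg = OnsetConfig(fs=300.0)
        with pytest.raises(ValueError):
            emg_onset.bandpass_emg(np.zeros(1000), cfg)


class TestHilbertEnvelope:
    def test_kernel_matches_closed_form(self):
        # odd taps are 2/(n*pi), even taps vanish
        assert emg_onset.hilbert_kernel(1) == pytest.approx(2 / np.pi)
        assert emg_onset.hilbert_kernel(2) == 0.0
        assert emg_onset.hilbert_kernel(3) == pytest.approx(2 / (3 * np.pi))
        assert emg_onset.hilbert_kernel(6) == 0.0

    def test_sinusoid_envelope_recovers_amplitude(self):
        fs = 1024.0
        t = np.arange(int(4 * fs)) / fs
        x = 2.5 * np.sin(2 * np.pi * 50 * t)
        H = emg_onset.hilbert_envelope(x)
        interior = H[int(0.5 * fs) : -int(0.5 * fs)]
        assert np.abs(interior - 2.5).max() / 2.5 < 0.02

    def test_nonnegative(self, rng):
        H = emg_onset.hilbert_envelope(rng.standard_normal(1000))
        assert np.all(H >= 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            emg_onset.hilbert_envelope(np.array([]))


class TestSmoothNormalize:
    def test_range_and_prenormalization_mean(self, rng):
        cfg = OnsetConfig(fs=1024.0)
        H = np.abs(rng.standard_normal(5000))
        E = emg_onset.smooth_normalize(H, cfg)
        assert E.values.min() == pytest.approx(-1.0)
        assert E.values.max() == pytest.approx(1.0)

    def test_matches_direct_convolution_oracle(self, rng):
        cfg = OnsetConfig(fs=1024.0)
        H = np.abs(rng.standard_normal(2000))
        W = np.hamming(cfg.m)
        W /= W.sum()
        padded = np.pad(H, (cfg.m // 2, cfg.m - 1 - cfg.m // 2), mode="edge")
        ET = np.convolve(padded, W, mode="valid")
        ET = ET - ET.mean()
        expected = 2 * (ET - ET.min()) / (ET.max() - ET.min()) - 1
        E = emg_onset.smooth_normalize(H, cfg)
        np.testing.assert_allclose(E.values, expected, atol=1e-12)

    def test_impulse_spreads_over_window_width(self):
        cfg = OnsetConfig(fs=1024.0)
        H = np.zeros(1000)
        H[500] = 1.0
        E = emg_onset.smooth_normalize(H, cfg)
        above = np.flatnonzero(E.values > 0)
        assert cfg.m * 0.3 < len(above) <= cfg.m + 2

    def test_constant_envelope_rejected(self):
        cfg = OnsetConfig(fs=1024.0)
        with pytest.raises(ValueError):
            emg_onset.smooth_normalize(np.full(1000, 2.0), cfg)


class TestBinaryState:
    def test_hand_worked_example(self):
        # threshold 2 * mean = 2*(-1.3/9) ~ -0.289; only positives exceed it
        E = emg_onset.EnvelopeSignal(
            np.array([-0.8, -0.9, -0.7, 0.9, 0.8, 0.7, -0.8, -0.9, -0.6]), fs=1024.0
        )
        cfg = OnsetConfig(fs=1024.0, alpha=2.0, l=100)  # l > N: update disabled
        S = emg_onset.binary_state(E, cfg)
        np.testing.assert_array_equal(S.states, [0, 0, 0, 1, 1, 1, 0, 0, 0])

    def test_threshold_below_range_gives_all_active(self):
        E = emg_onset.EnvelopeSignal(np.array([-0.5, -0.4, -0.6, -0.5]), fs=1024.0)
        cfg = OnsetConfig(fs=1024.0, alpha=3.0, l=100)  # th = 3*mean << min
        S = emg_onset.binary_state(E, cfg)
        assert np.all(S.states == 1)

    def test_beta_one_update_equals_global_mean(self, rng):
        # with beta=1 the updated threshold collapses to the global mean
        vals = rng.uniform(-1, 1, 40)
        E = emg_onset.EnvelopeSignal(vals, fs=1024.0)
        cfg = OnsetConfig(fs=1024.0, alpha=1.0, beta=1.0, l=10)
        S = emg_onset.binary_state(E, cfg)
        gm = vals.mean()
        expected = np.zeros(40, dtype=int)
        expected[:10] = vals[:10] >= 1.0 * gm   # first window: th_i = alpha*gm
        expected[10:] = vals[10:] >= gm
        np.testing.assert_array_equal(S.states, expected)


class TestFilterStates:
    def test_short_rest_gap_filled(self):
        cfg = OnsetConfig(fs=1024.0, TA=3, TN=1)
        S = emg_onset.filter_states(StateSequence(np.array([1, 0, 0, 1])), cfg)
        np.testing.assert_array_equal(S.states, [1, 1, 1, 1])

    def test_short_activity_run_zeroed(self):
        cfg = OnsetConfig(fs=1024.0, TA=1, TN=3)
        S = emg_onset.filter_states(StateSequence(np.array([0, 1, 1, 0])), cfg)
        np.testing.assert_array_equal(S.states, [0, 0, 0, 0])

    def test_all_zero_unchanged(self):
        cfg = OnsetConfig(fs=1024.0)
        S = emg_onset.filter_states(StateSequence(np.zeros(10, dtype=int)), cfg)
        assert not np.any(S.states)

    def test_boundary_rest_not_filled(self):
        cfg = OnsetConfig(fs=1024.0, TA=10, TN=1)
        S = emg_onset.filter_states(StateSequence(np.array([0, 0, 1, 1, 1, 0, 0])), cfg)
        np.testing.assert_array_equal(S.states, [0, 0, 1, 1, 1, 0, 0])

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60),
           st.integers(1, 10), st.integers(1, 10))
    @settings(max_examples=100, deadline=None)
    def test_idempotent(self, bits, ta, tn):
        cfg = OnsetConfig(fs=1024.0, TA=ta, TN=tn)
        once = emg_onset.filter_states(StateSequence(np.array(bits)), cfg)
        twice = emg_onset.filter_states(once, cfg)
        np.testing.assert_array_equal(once.states, twice.states)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60), st.integers(1, 8))
    @settings(max_examples=100, deadline=None)
    def test_larger_tn_never_adds_onsets(self, bits, ta):
        S = StateSequence(np.array(bits))
        counts = []
        for tn in (1, 3, 6, 12):
            cfg = OnsetConfig(fs=1024.0, TA=ta, TN=tn)
            counts.append(len(emg_onset.detect_onsets(emg_onset.filter_states(S, cfg))))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60), st.integers(1, 8))
    @settings(max_examples=100, deadline=None)
    def test_larger_ta_never_adds_rest_gaps(self, bits, tn):
        def interior_rest_gaps(states):
            from mrcp.emg_onset import _runs
            runs = _runs(states)
            return sum(1 for i, (v, _, _) in enumerate(runs)
                       if v == 0 and 0 < i < len(runs) - 1)

        counts = []
        for ta in (1, 3, 6, 12):
            cfg = OnsetConfig(fs=1024.0, TA=ta, TN=tn)
            out = emg_onset.filter_states(StateSequence(np.array(bits)), cfg)
            counts.append(interior_rest_gaps(out.states))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDetectOnsets:
    def test_rising_edge_index(self):
        S = StateSequence(np.array([0, 0, 1, 1, 0]))
        np.testing.assert_array_equal(emg_onset.detect_onsets(S), [2])

    def test_edge_onset_convention(self):
        S = StateSequence(np.array([1, 1, 0, 1]))
        np.testing.assert_array_equal(emg_onset.detect_onsets(S), [3])
        np.testing.assert_array_equal(
            emg_onset.detect_onsets(S, edge_onsets=True), [0, 3]
        )

    def test_no_transitions_empty(self):
        assert len(emg_onset.detect_onsets(StateSequence(np.zeros(5, dtype=int)))) == 0


class TestEndToEnd:
    def test_recovers_true_onsets_within_50ms(self, small_session):
        rec = small_session
        cfg = OnsetConfig(fs=rec.fs)
        detected, _ = emg_onset.detect_emg_onsets(rec.emg[0], cfg)
        assert len(detected) == len(rec.true_onsets)
        err_ms = np.abs(detected - rec.true_onsets) / rec.fs * 1000.0
        assert np.median(err_ms) <= 50.0
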