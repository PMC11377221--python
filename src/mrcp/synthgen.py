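"""Synthetic EEG/EMG cohort generator with known movement-onset ground truth.

Emulates the statistical structure that the downstream pipeline assumes:

* a readiness-potential (RP) template time-locked to each voluntary movement
  onset — a slow early negativity from roughly -1.75 s, a steep late
  negativity from roughly -0.75 s, a motor-potential trough near the onset,
  and a recovery toward baseline by about +1 s;
* background EEG mixing a dominant alpha-band idle rhythm, 1/f neural
  noise (with a 1 Hz spectral knee), and broadband white sensor noise, at
  an amplitude that buries the single-trial RP (the RP only emerges after
  averaging, as it does in real recordings);
* tibialis-anterior EMG bursts whose band-limited (20-200 Hz) carrier is
  modulated by a rising envelope at the true onset;
* optional additive artifacts: sub-2 Hz motion drift and powerline hum.

All generation is a pure function of (parameters, seed): the same seed
yields a bit-identical recording.

Units: EEG in microvolts, EMG in millivolts, time in samples at ``fs`` Hz
unless a value is explicitly labeled seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

#: channels ordered front-to-back so adjacent rows of the EEG array are
#: spatial neighbors (the classifier input is a channels x time grid)
DEFAULT_CHANNELS = ["FC1", "FCz", "FC2", "C1", "Cz", "C2", "CP1", "CP2"]

#: seconds of stillness that precede every onset (paradigm: stand still for
#: at least 5 s, then start walking at will)
MIN_REST_S = 5.0


@dataclass
class RPTemplate:
    """Piecewise-smooth readiness-potential waveform parameters.

    The waveform is zero before ``early_start``, ramps slowly to
    ``early_amp`` by ``late_start`` (early RP), ramps steeply to the
    motor-potential trough ``late_amp`` at ``mp_time`` (late RP / MP),
    and recovers to zero by ``mmp_end`` (movement-monitoring phase).
    Amplitudes are negative microvolts; times are seconds relative to
    movement onset.
    """

    early_start: float = -1.75
    late_start: float = -0.75
    early_amp: float = -3.0
    late_amp: float = -16.0
    mp_time: float = 0.0
    mmp_end: float = 1.0

    def __post_init__(self) -> None:
        if not (self.early_start < self.late_start < self.mp_time < self.mmp_end):
            raise ValueError(
                "require early_start < late_start < mp_time < mmp_end, got "
                f"{self.early_start}, {self.late_start}, {self.mp_time}, {self.mmp_end}"
            )
        if self.early_amp > 0 or self.late_amp > 0:
            raise ValueError("RP amplitudes must be negative (it is a negativity)")
        if self.late_amp > self.early_amp:
            raise ValueError("late_amp must be at least as negative as early_amp")


@dataclass
class SubjectProfile:
    """Per-subject generation parameters.

    rp_scale multiplies the RP template amplitudes; latency_jitter_sd is the
    SD (seconds) of the trial-to-trial shift between the cortical RP and the
    EMG onset, and rp_latency_mean that shift's subject-level mean (RP lead
    time varies substantially between people); eeg_noise_sd is the
    per-sample background-EEG SD in microvolts; erd_depth is the fractional
    alpha-band power suppression during movement preparation and execution
    (event-related desynchronization); emg_snr is the ratio of post-onset
    to baseline EMG RMS; left_gain attenuates the RP on left-leg trials
    (right-leg responses are typically stronger); contralateral_bias maps
    channel name -> gain.
    """

    rp_scale: float = 1.0
    latency_jitter_sd: float = 0.05
    rp_latency_mean: float = 0.0
    eeg_noise_sd: float = 18.0
    erd_depth: float = 0.4
    emg_snr: float = 8.0
    left_gain: float = 0.8
    contralateral_bias: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rp_scale < 0:
            raise ValueError("rp_scale must be >= 0")
        if self.emg_snr <= 0:
            raise ValueError("emg_snr must be > 0")


@dataclass
class SessionRecording:
    """Synchronized EEG + EMG arrays with ground-truth onsets."""

    eeg: np.ndarray              # (n_channels, n_samples) microvolts
    emg: np.ndarray              # (2, n_samples) millivolts
    fs: float                    # Hz
    channel_names: list[str]
    true_onsets: np.ndarray      # sample indices, strictly increasing
    leg_labels: list[str]        # per-trial "left"/"right"
    subject_id: int = 0
    session_id: int = 0
    profile: "SubjectProfile | None" = None  # generation ground truth

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        self.true_onsets = np.asarray(self.true_onsets, dtype=int)
        if self.eeg.shape[1] != self.emg.shape[1]:
            raise ValueError("EEG and EMG must have equal sample counts")
        if len(self.true_onsets) != len(self.leg_labels):
            raise ValueError("one leg label per onset required")
        if len(self.true_onsets) > 1 and np.any(np.diff(self.true_onsets) <= 0):
            raise ValueError("true_onsets must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """Monotone cubic ramp 0 -> 1 on [0, 1] with zero end slopes."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def rp_waveform(t_rel, template: RPTemplate | None = None) -> np.ndarray | float:
    """Evaluate the RP template at time(s) ``t_rel`` (seconds re onset).

    Piecewise cubic ramps: zero before ``early_start``, slow negative ramp
    to ``early_amp``, steep ramp to the ``late_amp`` trough at ``mp_time``,
    recovery to zero by ``mmp_end``. Total function of its input: no NaN,
    no error for any real ``t_rel``.
    """
    if template is None:
        template = RPTemplate()
    t = np.asarray(t_rel, dtype=float)
    out = np.zeros_like(t)

    # early RP: 0 -> early_amp
    seg = (t > template.early_start) & (t <= template.late_start)
    u = (t[seg] - template.early_start) / (template.late_start - template.early_start)
    out[seg] = template.early_amp * _smoothstep(u)

    # late RP: early_amp -> late_amp (monotonically more negative)
    seg = (t > template.late_start) & (t <= template.mp_time)
    u = (t[seg] - template.late_start) / (template.mp_time - template.late_start)
    out[seg] = template.early_amp + (template.late_amp - template.early_amp) * _smoothstep(u)

    # recovery: late_amp -> 0
    seg = (t > template.mp_time) & (t < template.mmp_end)
    u = (t[seg] - template.mp_time) / (template.mmp_end - template.mp_time)
    out[seg] = template.late_amp * (1.0 - _smoothstep(u))

    if np.isscalar(t_rel):
        return float(out)
    return out


def pink_noise(
    n_samples: int,
    rng: np.random.Generator,
    alpha: float = 1.0,
    fs: float = 1.0,
    knee_hz: float = 0.0,
) -> np.ndarray:
    """1/f^alpha noise, unit variance, via spectral shaping of white noise.

    ``knee_hz`` flattens the spectrum below that frequency (neural power
    spectra plateau at the lowest frequencies rather than diverging).
    """
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    eff = np.maximum(freqs, max(knee_hz, freqs[1] if n_samples > 1 else 1.0))
    scale = eff ** (-alpha / 2.0)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _alpha_rhythm(n_samples: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance narrowband 8-12 Hz idle rhythm (spectral shaping)."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.exp(-0.5 * ((freqs - 10.0) / 1.5) ** 2)
    x = np.fft.irfft(spec * shape, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _background_eeg(
    n_samples: int,
    sd: float,
    fs: float,
    rng: np.random.Generator,
    alpha_envelope: np.ndarray | None = None,
) -> np.ndarray:
    """Background EEG scaled to total SD ``sd`` (microvolts).

    Power split across the standard awake-EEG constituents: a dominant
    alpha-band idle rhythm, broadband white sensor noise, and 1/f neural
    background with a 1 Hz spectral knee. The sub-3 Hz delta band where
    the RP lives holds a few percent of total power, as in awake
    low-delta recordings, while the broadband SD stays large enough that
    single-trial RPs sit below the raw noise floor.

    ``alpha_envelope`` (same length, values in (0, 1]) modulates the
    alpha-rhythm amplitude over time — the carrier of event-related
    desynchronization around movements. SD normalization uses the
    unmodulated mixture so the envelope's dips are preserved.
    """
    pink = np.sqrt(0.06) * pink_noise(n_samples, rng, fs=fs, knee_hz=1.0)
    alpha = np.sqrt(0.64) * _alpha_rhythm(n_samples, fs, rng)
    white = np.sqrt(0.30) * rng.standard_normal(n_samples)
    scale = sd / max((pink + alpha + white).std(), 1e-12)
    if alpha_envelope is not None:
        alpha = alpha * alpha_envelope
    return scale * (pink + alpha + white)


def _erd_envelope(
    n_samples: int,
    fs: float,
    onsets: np.ndarray,
    jitter_s: np.ndarray,
    depth: float,
) -> np.ndarray:
    """Alpha-amplitude envelope with a smooth dip around each movement:
    desynchronization begins about 1.5 s before onset, is deepest through
    execution, and recovers by about +1.5 s."""
    t = np.arange(n_samples) / fs
    dip = np.zeros(n_samples)
    for onset, jit in zip(onsets, jitter_s):
        rel = t - onset / fs - jit
        fall = _smoothstep((rel + 1.5) / 1.0)      # -1.5 .. -0.5 s
        rise = _smoothstep((rel - 0.5) / 1.0)      # +0.5 .. +1.5 s
        dip += fall * (1.0 - rise)
    return 1.0 - depth * np.clip(dip, 0.0, 1.0)


def _blink_artifacts(
    n_samples: int,
    fs: float,
    n_channels: int,
    rng: np.random.Generator,
    rate_hz: float = 0.12,
    amp_range: tuple[float, float] = (30.0, 80.0),
) -> np.ndarray:
    """Ocular-artifact transients: smooth ~0.4 s monophasic pulses with a
    front-to-back amplitude gradient, at random times (Poisson-like)."""
    out = np.zeros((n_channels, n_samples))
    n_events = rng.poisson(rate_hz * n_samples / fs)
    width = int(0.2 * fs)
    gradient = np.linspace(1.0, 0.35, n_channels)  # frontal rows largest
    for _ in range(n_events):
        center = rng.integers(0, n_samples)
        amp = rng.uniform(*amp_range) * rng.choice([-1.0, 1.0])
        lo = max(0, center - 2 * width)
        hi = min(n_samples, center + 2 * width)
        t = np.arange(lo, hi)
        pulse = amp * np.exp(-0.5 * ((t - center) / (width / 2.0)) ** 2)
        out[:, lo:hi] += gradient[:, None] * pulse
    return out


def _emg_band(fs: float) -> tuple[float, float]:
    """EMG carrier band: 20-200 Hz, upper edge clipped below Nyquist."""
    return (20.0, min(200.0, 0.4 * fs))


def emg_burst(
    n_samples: int,
    onset_idx: int,
    fs: float,
    profile: SubjectProfile | None = None,
    *,
    active_duration: float | None = None,
    rise_time: float = 0.1,
    baseline_sd: float = 0.01,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One EMG channel (mV): baseline noise, then a modulated burst at onset.

    The carrier is Gaussian noise band-passed to 20-200 Hz; the envelope
    rises as a raised cosine over ``rise_time`` seconds at ``onset_idx`` and
    (if ``active_duration`` is given) falls symmetrically at the burst end.
    Post-onset RMS is ``profile.emg_snr`` times the baseline RMS.
    """
    if profile is None:
        profile = SubjectProfile()
    if not 0 <= onset_idx < n_samples:
        raise ValueError(f"onset_idx {onset_idx} out of range [0, {n_samples})")
    if rng is None:
        rng = np.random.default_rng(profile.seed)

    baseline = baseline_sd * rng.standard_normal(n_samples)

    carrier = rng.standard_normal(n_samples)
    sos = signal.butter(4, _emg_band(fs), btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfiltfilt(sos, carrier)
    carrier = carrier / carrier.std()

    env = np.zeros(n_samples)
    n_rise = max(1, int(round(rise_time * fs)))
    t_idx = np.arange(n_samples)
    rise = 0.5 * (1.0 - np.cos(np.pi * np.clip((t_idx - onset_idx) / n_rise, 0.0, 1.0)))
    env = np.where(t_idx >= onset_idx, rise, 0.0)
    if active_duration is not None:
        off_idx = onset_idx + int(round(active_duration * fs))
        fall = 0.5 * (1.0 + np.cos(np.pi * np.clip((t_idx - off_idx) / n_rise, 0.0, 1.0)))
        env = env * np.where(t_idx >= off_idx, fall, 1.0)

    return baseline + profile.emg_snr * baseline_sd * env * carrier


def add_artifacts(
    eeg: np.ndarray,
    fs: float,
    drift_freq: float = 0.2,
    drift_amp: float = 0.0,
    powerline_freq: float = 50.0,
    powerline_amp: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Add motion drift and powerline hum to EEG; strictly additive.

    The drift is a shared-phase sinusoid below 2 Hz (the motion-artifact
    band) with small per-channel gain variation; the powerline term is a
    fixed-frequency sinusoid. The contamination is reproducible from
    (parameters, seed), so output - input recovers it exactly.
    """
    eeg = np.asarray(eeg, dtype=float)
    if drift_amp != 0.0 and not (0.0 < drift_freq < 2.0):
        raise ValueError(
            f"drift_freq must lie in (0, 2) Hz to model a motion artifact, got {drift_freq}"
        )
    rng = np.random.default_rng(seed)
    n_ch, n_samp = eeg.shape
    t = np.arange(n_samp) / fs
    out = eeg.copy()
    if drift_amp != 0.0:
        phase = rng.uniform(0, 2 * np.pi)
        gains = 1.0 + 0.1 * rng.standard_normal(n_ch)
        out = out + drift_amp * gains[:, None] * np.sin(2 * np.pi * drift_freq * t + phase)
    if powerline_amp != 0.0:
        phase = rng.uniform(0, 2 * np.pi)
        out = out + powerline_amp * np.sin(2 * np.pi * powerline_freq * t + phase)
    return out


def _channel_gains(channel_names: list[str], profile: SubjectProfile) -> np.ndarray:
    gains = np.ones(len(channel_names))
    if profile.contralateral_bias:
        for i, name in enumerate(channel_names):
            gains[i] = profile.contralateral_bias.get(name, 1.0)
    return gains


def make_session(
    template: RPTemplate | None = None,
    profile: SubjectProfile | None = None,
    n_trials: int = 10,
    fs: float = 1024.0,
    *,
    rest_duration: float = 6.0,
    active_duration: float = 3.0,
    blink_rate: float = 0.0,
    channel_names: list[str] | None = None,
    subject_id: int = 0,
    session_id: int = 0,
) -> SessionRecording:
    """Generate one synthetic session of ``n_trials`` voluntary movements.

    Each trial is ``rest_duration`` seconds of stillness (>= 5 s, matching
    the paradigm) followed by ``active_duration`` seconds of walking. The
    EEG is per-channel background noise plus the RP time-locked to each
    onset (with per-trial latency jitter); the EMG holds a burst at each
    onset on both tibialis-anterior channels.
    """
    if template is None:
        template = RPTemplate()
    if profile is None:
        profile = SubjectProfile()
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rest_duration < MIN_REST_S:
        raise ValueError(f"rest_duration must be >= {MIN_REST_S} s (paradigm)")
    if channel_names is None:
        channel_names = list(DEFAULT_CHANNELS)

    rng = np.random.default_rng(profile.seed)
    trial_len = int(round((rest_duration + active_duration) * fs))
    n_samples = n_trials * trial_len
    onsets = np.array(
        [k * trial_len + int(round(rest_duration * fs)) for k in range(n_trials)]
    )
    legs = ["right" if rng.uniform() < 0.5 else "left" for _ in range(n_trials)]
    jitter = profile.rp_latency_mean + rng.normal(
        0.0, profile.latency_jitter_sd, size=n_trials
    )

    gains = _channel_gains(channel_names, profile)
    t = np.arange(n_samples) / fs

    rp_track = np.zeros(n_samples)
    for k, onset in enumerate(onsets):
        leg_gain = 1.0 if legs[k] == "right" else profile.left_gain
        t_rel = t - onset / fs - jitter[k]
        # template support is [early_start, mmp_end]; evaluate only nearby
        lo = max(0, int((onset / fs + jitter[k] + template.early_start - 0.1) * fs))
        hi = min(n_samples, int((onset / fs + jitter[k] + template.mmp_end + 0.1) * fs))
        rp_track[lo:hi] += leg_gain * rp_waveform(t_rel[lo:hi], template)

    # alpha suppression on task engagement: desynchronization around each
    # movement, shared across the (small, central) electrode patch
    erd_env = _erd_envelope(n_samples, fs, onsets, jitter, profile.erd_depth)
    eeg = np.empty((len(channel_names), n_samples))
    for c in range(len(channel_names)):
        eeg[c] = (
            profile.rp_scale * gains[c] * rp_track
            + _background_eeg(n_samples, profile.eeg_noise_sd, fs, rng,
                              alpha_envelope=erd_env)
        )
    if blink_rate > 0:
        eeg += _blink_artifacts(n_samples, fs, len(channel_names), rng,
                                rate_hz=blink_rate)

    # bursts never overlap (one per trial), so one band-limited carrier per
    # channel modulated by the summed per-trial envelopes suffices
    idx = np.arange(n_samples)
    n_rise = max(1, int(round(0.1 * fs)))
    env = np.zeros(n_samples)
    for onset in onsets:
        rise = 0.5 * (1.0 - np.cos(np.pi * np.clip((idx - onset) / n_rise, 0, 1)))
        off_idx = onset + int(round(active_duration * fs)) - n_rise
        fall = 0.5 * (1.0 + np.cos(np.pi * np.clip((idx - off_idx) / n_rise, 0, 1)))
        env += np.where(idx >= onset, rise, 0.0) * np.where(idx >= off_idx, fall, 1.0)

    sos = signal.butter(4, _emg_band(fs), btype="bandpass", fs=fs, output="sos")
    emg = np.empty((2, n_samples))
    for ch in range(2):
        carrier = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
        carrier /= carrier.std()
        emg[ch] = 0.01 * rng.standard_normal(n_samples) + profile.emg_snr * 0.01 * env * carrier

    return SessionRecording(
        eeg=eeg,
        emg=emg,
        fs=fs,
        channel_names=channel_names,
        true_onsets=onsets,
        leg_labels=legs,
        subject_id=subject_id,
        session_id=session_id,
        profile=profile,
    )


@dataclass
class CohortVariability:
    """Between-subject / between-session parameter spreads.

    rp_scale_sd is the SD of the log of the subject-level RP gain;
    session_gain_sd shifts each session's effective RP gain (cross-temporal
    drift); session_latency_sd shifts each session's mean RP latency.
    """

    rp_scale_sd: float = 0.35
    noise_sd_range: tuple[float, float] = (15.0, 21.0)
    bias_sd: float = 0.1
    #: per-subject range of trial-to-trial RP-vs-EMG latency SD (seconds);
    #: self-paced movements show large spontaneous variability
    trial_jitter_range: tuple[float, float] = (0.08, 0.16)
    #: range of the RP topography focus (fractional row index over the
    #: front-to-back channel grid): electrode-cap placement and individual
    #: motor-cortex anatomy move the potential's scalp maximum
    topo_center_range: tuple[float, float] = (1.5, 5.5)
    topo_width: float = 2.2
    subject_latency_range: tuple[float, float] = (-0.2, 0.2)
    erd_depth_range: tuple[float, float] = (0.25, 0.55)
    session_gain_sd: float = 0.15
    session_latency_sd: float = 0.04


def make_cohort(
    n_subjects: int = 5,
    n_sessions: int = 2,
    base_template: RPTemplate | None = None,
    variability: CohortVariability | None = None,
    seed: int = 0,
    *,
    n_trials: int = 10,
    fs: float = 1024.0,
    **session_kwargs,
) -> list[SessionRecording]:
    """Generate ``n_subjects * n_sessions`` recordings.

    Subject-level parameters (RP gain, noise level, scalp topography of
    the RP focus, mean RP lead time) are drawn once per subject and reused
    across that subject's sessions; session-level gain and latency offsets
    differ between sessions to emulate cross-temporal drift. Deterministic
    in the master seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if base_template is None:
        base_template = RPTemplate()
    if variability is None:
        variability = CohortVariability()
    master = np.random.default_rng(seed)

    recordings: list[SessionRecording] = []
    for s in range(n_subjects):
        rp_scale = float(np.exp(master.normal(0.0, variability.rp_scale_sd)))
        noise_sd = float(master.uniform(*variability.noise_sd_range))
        center = master.uniform(*variability.topo_center_range)
        bias = {}
        for row, name in enumerate(DEFAULT_CHANNELS):
            bump = np.exp(-0.5 * ((row - center) / variability.topo_width) ** 2)
            bias[name] = float(
                (0.35 + 0.9 * bump)
                * (1.0 + variability.bias_sd * master.standard_normal())
            )
        subj_latency_sd = float(master.uniform(*variability.trial_jitter_range))
        subj_latency_mean = float(master.uniform(*variability.subject_latency_range))
        subj_erd = float(master.uniform(*variability.erd_depth_range))
        for sess in range(n_sessions):
            gain_shift = float(np.exp(master.normal(0.0, variability.session_gain_sd)))
            sess_latency = float(master.normal(0.0, variability.session_latency_sd))
            sess_seed = int(master.integers(0, 2**31 - 1))
            profile = SubjectProfile(
                rp_scale=rp_scale * gain_shift,
                latency_jitter_sd=subj_latency_sd,
                rp_latency_mean=subj_latency_mean + sess_latency,
                eeg_noise_sd=noise_sd,
                erd_depth=subj_erd,
                contralateral_bias=bias,
                seed=sess_seed,
            )
            recordings.append(
                make_session(
                    base_template,
                    profile,
                    n_trials=n_trials,
                    fs=fs,
                    subject_id=s,
                    session_id=sess,
                    **session_kwargs,
                )
            )
    return recordings
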