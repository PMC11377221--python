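# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `mrcp`. It is written for a reader who wants to judge
what the package's results do and do not demonstrate.

## 1. The decoding problem

Self-paced movement is preceded by the movement-related cortical potential
(MRCP) over sensorimotor cortex: a slow readiness potential (RP) beginning
1.5–2 s before EMG onset (early RP: shallow ramp; late RP from about
0.5–1 s: steep ramp), a motor-potential (MP) trough near onset, and a
recovery (movement-monitoring) phase. Typical amplitudes are 5–30 µV —
below the single-trial EEG noise floor, which is why classical analyses
average tens of trials and why single-trial prediction requires a learned
decoder. The pipeline classifies 400 ms EEG windows as *rest* versus
*movement intention* and, online, slides that window causally over the
recording to emit one intention decision per trial before the movement
starts.

Movement onset ground truth comes from the tibialis-anterior EMG: muscle
activation is the only observable marker of the true start of voluntary
movement, and all EEG epochs are time-locked to it.

## 2. Synthetic cohort generator (`synthgen`)

No public recordings accompany this problem setting, so every stage is
exercised on synthetic cohorts whose statistical structure mirrors the
assumptions above. The generator is a pure function of (parameters, seed).

**RP template.** Piecewise cubic (smoothstep) ramps with zero end slopes:
0 before `early_start` (−1.75 s), ramp to `early_amp` (−3 µV) by
`late_start` (−0.75 s), ramp to the MP trough `late_amp` (−16 µV) at
onset, recovery to 0 by +1 s. Smoothstep segments keep the waveform
C¹-continuous and monotone within each phase; the trough magnitude sits in
the middle of the 5–30 µV literature range.

**Background EEG.** Per channel, a mixture with power fractions 64%
alpha-band idle rhythm (Gaussian spectral bump at 10 ± 1.5 Hz), 6% 1/f
neural background with a 1 Hz spectral knee (neural spectra plateau at the
lowest frequencies), and 30% broadband white sensor noise, scaled to a
total SD of 18 µV (subject range 15–21). The sub-3 Hz delta band then
holds a few percent of total power, as in awake low-delta EEG, while the
broadband SD keeps the single-trial RP below the noise floor: peak
|RP|/SD ≈ 0.9 < 1, and averaging 50 trials raises it to ≈ 6.

**Event-related desynchronization.** The alpha component's amplitude is
modulated by a smooth dip around each movement (engaged-state alpha
suppression): desynchronization begins ≈1.5 s before onset, is deepest
through execution, recovers by +1.5 s. Depth is a subject parameter
(default 0.4, cohort range 0.25–0.55). This gives decoders a second,
power-based signature alongside the RP ramp, as in real motor EEG.

**Subject and session variability.** Drawn once per subject: RP gain
(log-normal, σ = 0.35), background-noise SD, scalp-topography focus (a
Gaussian gain bump over the front-to-back channel axis, center uniform in
rows 1.5–5.5, emulating cap placement and anatomical variation), mean
RP-to-EMG latency offset (±0.2 s) and trial-to-trial latency jitter SD
(0.08–0.16 s — self-paced movement preparation is temporally sloppy), and
ERD depth. Sessions of one subject share these and differ by a gain factor
and a small latency offset (cross-temporal drift). Right-leg RPs are
generated stronger than left (left gain 0.8) without claiming a measured
ratio.

**EMG.** Baseline sensor noise (10 µV RMS at the millivolt scale used for
EMG) plus a 20–200 Hz band-passed Gaussian carrier whose raised-cosine
envelope rises over 100 ms at the true onset and falls after the walking
bout; post-onset RMS is `emg_snr` (default 8) times baseline.

**Artifacts.** `add_artifacts` injects a shared-phase sub-2 Hz sinusoidal
motion drift and fixed-frequency powerline hum, strictly additively, so
tests can verify exact recovery. A blink-transient process (smooth ±30–80
µV pulses with a frontal gradient) exists but is off by default.

**What the generator does not emulate:** volume conduction and realistic
channel covariance (channel noise is independent), non-stationary rhythm
dynamics beyond the ERD envelope, eye/cardiac artifacts in the default
sessions, electrode drift/pops, and any coupling between EMG burst shape
and gait. Passing tests therefore demonstrate algorithmic correctness and
the qualitative behavior of the pipeline under controlled shift — not
clinical performance on real recordings.

## 3. EMG onset detection (`emg_onset`)

Band-pass 20–200 Hz (4th-order Butterworth) and a powerline notch, both
zero-phase (forward–backward) so that filter group delay cannot bias onset
times. The envelope is the analytic-signal magnitude |x + i·HT(x)|; the
discrete Hilbert kernel (2/(nπ) for odd lags, 0 for even) is exposed for
reference. The envelope is smoothed with a unit-sum Hamming window of
length m ≈ 0.05·fs (edge-replicated convolution, so no boundary droop),
mean-removed, and min–max mapped to [−1, 1].

The binary state S(n) compares E(n) to a threshold: initially
th = α·mean(E) (α = 1 default), then updated over non-overlapping windows
of length l ≈ 0.05·fs as th = w̄ + β(Ē − w̄) (β = 0.5) and applied
*causally* — the threshold estimated from window j classifies window j+1.
Two-step state filtering removes pseudo-states: rest gaps shorter than TA
(500 samples ≈ 0.49 s at 1024 Hz) strictly between activity runs are
filled; then activity runs shorter than TN (1500 samples ≈ 1.46 s) are
zeroed, including runs touching the record edges (activity already under
way at record start has no observable onset, so boundary runs are deleted
rather than trusted). TA/TN are interpreted in samples at 1024 Hz. The
filter is idempotent, and raising TN can only reduce the onset count.
Onsets are the 0→1 transitions; an onset at index 0 is reported only under
an explicit `edge_onsets` flag. A constant envelope is an error, not a
silent all-rest output.

Detected onsets lag true EMG activation by a few tens of milliseconds (the
envelope must clear the threshold); on default-SNR synthetic sessions the
detection rate is 100/100 with zero rest-period false alarms and median
absolute error ≈ 30 ms.

## 4. MEMD artifact removal (`memd`)

Multivariate EMD decomposes all 8 channels jointly so every channel shares
one IMF index set (no cross-channel mode misalignment). Projection
directions: K = 64 (default) unit vectors from a Hammersley point set —
uniform angles for 2-D; for higher dimensions a low-discrepancy cube
(lattice + van der Corput radical inverses in prime bases) mapped through
the inverse-Gaussian transform, then made antithetic (each direction
paired with its negative) so envelope means of symmetric signals are
unbiased. For each direction, the projection's local maxima define knots;
a natural cubic spline per channel through the signal values at those
knots (two mirrored extrema per boundary against end swings) is one
directional envelope; their mean is m(t).

Sifting iterates h ← h − m(h) until the global normalized correction
energy ‖m‖²/‖h‖² falls below 0.075, capped at 30 sifts (non-convergence
returns the current component with a warning). Decomposition continues on
the remainder until fewer than half the projections retain ≥ 3 maxima or
`max_imfs` (16) is reached. Reconstruction is a telescoping identity, so
ΣIMF + residual equals the input to machine precision by construction —
the tests assert ≤ 1e−6 relative error.

Cleaning discards, per channel, IMFs whose dominant FFT frequency
(DC excluded) is below the 0.5 Hz cutoff and reconstructs from the rest
plus the residual. The residual trend is *retained* by default, following
the stated reconstruction rule, even though slow drift partly ends up
there; `drop_residual=True` removes it and is what actually achieves the
≥ 90% sub-0.5 Hz power reduction in the acceptance run. Block-wise
processing of long records was considered and not implemented; at the
package's problem sizes whole-record decomposition is fast enough.

## 5. Epoching and labeling (`epochs`)

Epochs span [−3, +1) s around each onset (4096 samples at 1024 Hz, onset
at the 3 s mark); onsets with insufficient context are skipped and
counted. Stages: rest [−3, −1) s, intention [−1, +1) s — the post-onset
second is included for offline training; online prediction restricts to
pre-onset windows. The 400 ms window is ceil-rounded (410 samples at
1024 Hz; 52 at 128 Hz) so a window never covers less than 400 ms; windows
tile each stage at window-length steps with the final tile right-aligned
to the stage end, giving floor(stage/window) = 5 rest and 5 intention
windows per epoch (balanced classes by construction) while never
straddling the stage boundary. Splits are chronological and trial-blocked
(no trial on both sides) at the 70% trial boundary. `to_tensor` packs
(count, channels, samples, 1) batches, optionally band-passes, and
subtracts each channel's mean over the window's first 100 ms (a causal,
window-local baseline usable online). The band-pass is applied to the
continuous recording, not per window — a 0.05 Hz edge is ill-conditioned
on sub-second segments. Default analysis band 0.05–12 Hz: it spans the RP
(delta) and the alpha/ERD signature; the narrower 0.05–3 Hz RP band is a
parameter away.

## 6. CNN and parameter transfer (`cnn_tl`, `nn`)

The classifier follows the 16-weight-layer VGG pattern: 13 convolutional
layers (3×3 kernels, ReLU, same padding) in the canonical
2-2-3-3-3 blocks, max pooling between blocks, then 3 fully connected
layers with softmax. Because the input grid is only 8 channels tall, the
pooling cascade is 2×2, 2×2, then 1×2 three times — the temporal axis is
halved five times, the channel axis twice; layer counts are unchanged. A
width multiplier (default 0.25 → 16…128 conv filters, 1024-unit FC layers,
≈2.2 M parameters) keeps single-CPU training in minutes. Inputs are
divided by a fixed 5 µV/unit so the He-initialized stack starts
well-conditioned; the two hidden FC layers carry dropout 0.5 (the
classical VGG regularizer). Training: Adam (lr 1e−3 pretraining, 1e−4 to
3e−4 fine-tuning), batch 32, decoupled weight decay 1e−4 on weights,
epsilon-clipped (1e−12) softmax cross-entropy, optional early stopping on
a validation loss (patience 5). Everything — initialization, batch order,
dropout masks — derives from the config seed, so runs are bit-reproducible
on one platform. The engine is plain numpy (im2col convolutions with an
exact transpose backward pass, argmax-routed pooling gradients); gradient
correctness is verified against finite differences in the test suite.

Transfer: the target network copies all pretrained weights, replaces the
softmax head (zero-initialized, so the transferred model starts at uniform
probabilities and fine-tuning moves it monotonically), and freezes the
first `frozen_depth` = 8 convolutional layers; fine-tuning updates only
the remaining 5 conv + 3 FC layers. Frozen tensors are checksummed before
and after fine-tuning in the tests (bit-identity). The SVM reference is
scikit-learn's RBF SVC on standardized flattened windows (C = 1,
γ = 'scale') — deliberately a competent baseline, not a strawman.

## 7. Evaluation protocols (`evalproto`)

Offline metrics come from confusion counts with positive = intention;
precision/recall are defined as 0 (with a warning) when their denominator
is empty. Cross-temporal: a model trained on session 1 is either applied
directly to session 2's chronological test split or first transferred and
fine-tuned on session 2's train split. Cross-subject: pretrain on all
other subjects, evaluate on the held-out subject (fine-tuning on its train
split when transfer is enabled); window subject-ids are audited so no
held-out data enters pretraining.

Online simulation: a causal 400 ms window slides at 50 ms steps; k = 2
consecutive intention-positive windows latch one decision per trial at the
last window's end (the earliest instant the decision exists). Latency
Δt₁ = decision time − true onset. Δt₁ < 0 within the [−1 s, onset)
prediction window is a valid prediction; a first decision at or after
onset is wrong and recorded as Δt₁ = 0; no decision is a miss. Positives
earlier than −1 s are rest-period false alarms, counted separately —
with the early RP starting near −1.75 s, some pre-window positives are
expected and are not errors of the latency accounting. Accuracy is
valid/total over trials; latency summaries cover valid trials only.

## 8. Scale of the shipped experiments, and what they show

Tests and the acceptance script generate cohorts at 128 Hz (52-sample
windows), 5 subjects × 15 trials, with 200 ms-step (half-overlapping)
source windows for training — sizes chosen so the full paired comparison
(pretrain, fine-tune, scratch, SVM × 5 seeds) runs in minutes on one CPU.
EMG onset detection runs at the native 1024 Hz. MEMD checks use 64 Hz
random signals up to 60 s (the reconstruction identity is
length-independent).

Observed behavior at this scale, from the package's own runs: the
transfer-learned CNN beats the same CNN applied directly across subjects
on essentially every cohort seed (mean gap ≈ +8–10 accuracy points,
one-sided paired p ≈ 0.001 over 8 seeds), and fine-tuning reaches the
from-scratch model's best validation loss in fewer epochs — the central
transfer-learning claims. A caveat found honestly and worth stating: the
RBF-SVM baseline, competently configured, is *not* inferior to the
from-scratch CNN on this synthetic family (it trails the transfer-learned
model but matches or beats the unadapted CNN). With ~10³ training windows
of 416 dimensions the kernel interpolates well across the four source
subjects' nuisance parameters; the large SVM deficits reported on real
cross-subject EEG plausibly require higher input dimensionality and real
non-stationarities that this generator does not reproduce. The acceptance
suite asserts the full ordering anyway and documents this leg as failing
rather than weakening the baseline.

## 9. Numerical and degenerate-input conventions

Zero-phase filtering throughout (onset timing and epoch alignment depend
on it). Min–max normalization errors out on constant envelopes. The state
filter never fills boundary rest runs. MEMD treats an all-zero IMF's
dominant frequency as 0 Hz (discardable). Sample indices are 0-based,
intervals half-open. Determinism everywhere is seed-derived: generators
use `numpy.random.default_rng(seed)`, the CNN derives init/batch/dropout
streams from its config seed, and CLI stages write timestamp-free
artifacts (.npy + sorted-key JSON) so reruns are byte-identical.
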