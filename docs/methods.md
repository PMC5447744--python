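# Methods

## Problem and study design

The package implements a single-trial P300 detection study. In an
oddball paradigm, frequent non-target stimuli (probability 0.83) are
mixed with rare target (0.135) and distractor (0.035) stimuli at a
fixed 1 Hz stimulation rate; attended targets elicit the P300, a broad
positive event-related potential peaking roughly 300–500 ms
post-stimulus over centro-parietal sites, buried in ongoing EEG.
The classification design is cross-subject: classifiers are trained
once on a pool merged from 4 subjects and evaluated, frozen, on 11
different subjects, so test performance measures generalization to
unseen individuals rather than per-user calibration.

A session records 19 channels at 1 kHz and runs in three phases, each
continuing until 30 target stimuli have occurred (≈90 targets and
≈550–650 non-targets per session).

## Synthetic sessions

The simulator generates this design end-to-end so the pipeline is
testable without any recordings.

**Stimulus track.** Codes are drawn i.i.d. with the protocol
probabilities at exact 1 s spacing; marker strings default to the
BrainVision-style codes `S  2` (target), `S  4` (non-target) and `S  8`
(distractor). Phases are concatenated into one continuous recording
with phase boundaries kept as metadata; inter-phase breaks are not
simulated.

**Background EEG** is the sum of three zero-mean components per
channel, with defaults chosen as conventional magnitudes for scalp EEG
(the study the design derives from reports no subject-level amplitude
or noise figures):

| component | default | role |
|---|---|---|
| pink noise, 1/f | sd 4 μV | dominant low-frequency EEG background |
| alpha rhythm, 10 Hz sinusoid, random phase per channel | amplitude 2 μV | the strongest rhythmic component of resting EEG |
| white noise | sd 1 μV | sensor/amplifier noise floor |

Pink noise is produced by spectral shaping of white noise (FFT padded
to a fast length) and rescaled to its target sd exactly.

**Event responses.** A target adds a Gaussian bump in time —
amplitude × exp(−(t−latency)²/2·width²) — scaled per channel by a
fixed topography peaking at Pz (gain 1.0) and falling off frontally;
the Gaussian is a deliberate minimal model: two parameters (latency,
width) control everything, and the true single-trial P300 shape is not
identifiable from the source study anyway. Defaults: latency
400 ms ± 30 ms trial-to-trial jitter, width (Gaussian sd) 60 ms,
amplitude per subject drawn uniformly from 2–10 μV — conventional
single-trial peak heights. Non-targets add nothing; distractors add an
optional earlier, frontally weighted positivity (P3a-like) and default
off, but distractor markers always appear in the stimulus track so the
"ignored during epoching" path is exercised.

**Randomness.** Every stage draws from `numpy` generators spawned from
a master seed (sequence, background and responses in separate
substreams), so a session with amplitude A equals the amplitude-0
session plus the deterministic response track sample-for-sample when
jitter is off, and whole cohorts rerun bit-identically.

**What the simulator does not emulate** — and hence what passing tests
do not show about real data: eye-blink/EMG artifacts, electrode drift
and impedance effects, non-stationary background statistics,
subject-specific latency topographies, and overlapping responses from
sub-second stimulation. Synthetic cohorts with the default amplitudes
are *easier* than real recordings (the full study here reaches ≈97 %
accuracy versus ≈65–69 % on real data), so the synthetic study
validates the machinery and relative behavior of the classifiers, not
absolute real-data performance.

## Epoching and features

Trials span the half-open window [−500, +1000) ms around each target /
non-target marker (1500 samples at 1 kHz, onset at sample 500); marker
codes are matched after whitespace normalization because BrainVision
writers pad differently; trials overrunning a recording edge are
dropped and counted. Feature extraction is the windowed-means
paradigm:

1. per-trial, per-channel subtraction of the mean over the 500 ms
   pre-stimulus baseline;
2. means of 11 consecutive 50 ms windows from 150 to 700 ms
   post-stimulus (half-open in ms, mapped to samples by floor(t·fs/1000));
3. channel-major concatenation → 19 × 11 = 209 features, with
   `channel:start_ms` names kept so the layout is auditable;
4. division of each trial vector by its Euclidean norm ("length"
   normalization; rows are then scale-invariant).

## Classifiers

**Stacked sparse autoencoder (SAE).** Four sigmoid autoencoders with
hidden sizes 130, 100, 50, 20 are pretrained greedily, each on the
previous layer's encodings, minimizing

  J = mean((x̂ − x)²) + (λ/2)‖W‖² + β Σⱼ KL(ρ ‖ ρ̂ⱼ),

with λ = 0.004, β = 4, ρ = 0.2 and ρ̂ⱼ the batch-mean activation of
hidden unit j (clamped to [1e−6, 1−1e−6] to keep the KL finite, with a
logged warning). Pretraining runs at most 200 epochs per layer. A
softmax head is then trained for 200 iterations on the deepest code
(zero-initialized — the problem is convex — hence deterministic), and
the assembled 209-130-100-50-20-2 network is fine-tuned end-to-end on
the plain cross-entropy. Because the sigmoid decoder can only
reproduce (0, 1) values, each feature column is affinely mapped to
[0.1, 0.9] before the first autoencoder; the map is stored in the
model and re-applied at inference. Decoder weights are untied from
encoder weights.

**Optimizer.** All training uses deterministic full-batch gradient
descent with momentum 0.9 and an adaptive step: an improving step
multiplies the rate by 1.05 (capped at 100× the initial 0.1), a
worsening step is rejected, halves the rate and resets momentum.
Exactly one cost/gradient evaluation per iteration; the accepted cost
is monotone, which also guarantees the "training never increases the
cost" contract. Weights initialize uniformly in
±√(6/(fan_in+fan_out)); biases at zero; biases are excluded from the
L2 penalty. Every analytic gradient (autoencoder, softmax, full
network) is verified against central finite differences at ≤1e−6
relative error in the test suite — the module's core oracle.

**Fine-tuning and validation.** 20 % of the training pool (randomly
selected, seeded) is held out; network training keeps the parameters
with the lowest validation cross-entropy seen during descent
(keep-best early stopping). The fine-tuning iteration count defaults
to 200 and is configuration-exposed, as the source study prints no
value for it. LDA, which has no iteration budget, trains on the full
pool.

**MLP baseline** shares the architecture, transfer functions, scaler,
forward pass and optimizer with the SAE (a parameter-transplant test
enforces the shared code path) but starts from random initialization
with no pretraining and trains 1000 iterations.

**Shrinkage LDA baseline.** The pooled within-class covariance
S = XᶜᵀXᶜ/n (class-centered rows) is shrunk toward ν·I with
ν = trace(S)/d and analytic Ledoit–Wolf intensity
λ* = min(b̄², d²)/d², b̄² = (Σₖ‖xₖ‖⁴ − n‖S‖²_F)/n²,
d² = ‖S − νI‖²_F, clipped to [0, 1] — the standard recommendation for
high-dimensional ERP features. The weight vector is
w = S_shrunk⁻¹(m₁ − m₀) with the threshold at the projected midpoint
of the class means (classes are balanced by construction, so no prior
weighting). A trial exactly on the boundary goes to non-target.

## Trial-set assembly and evaluation

Training: from each training subject, all targets plus an equal-count
uniform random subset of its non-targets; the union is shuffled.
Testing, per subject: all targets plus the *first* (chronological)
equal number of non-targets — balanced, so chance is exactly 50 %.
Accuracy, precision and recall (target = positive class) are reported
in percent per subject and averaged across subjects; undefined ratios
(zero denominator) are reported as NaN with a warning. Classifier
pairs are compared with McNemar's test on pooled test-set predictions:
exact two-sided binomial when the discordant count b+c < 25 (threshold
configuration-exposed), otherwise chi-square with continuity
correction; b+c = 0 gives p = 1. Per-subject McNemar is available as
an option. `StudyConfig.repetitions` > 1 retrains with fresh seeds and
averages the metrics — a model-selection aid; the McNemar comparison
always uses the first trained instance.

## Numerical and interface choices

- Epoch windows and feature windows are half-open; at 1 kHz this gives
  exactly 1500 samples per trial and 50 samples per window.
- Internal container: single-file HDF5 (signal, markers, JSON
  metadata), lossless round-trip. BrainVision reading goes through MNE
  with `Stimulus/` prefixes stripped so marker codes come back
  verbatim; a minimal INT_16 multiplexed BrainVision writer exists for
  fixtures and interoperability, and the MNE round-trip is its
  cross-check (default resolution 0.1 μV per integer step).
- Softmax ties (exactly equal probabilities) break to the lower class
  index, i.e. non-target.
- `run_study` seeds: one master seed is spawned into substreams for
  cohort profiles, simulation, training-set assembly, the validation
  split and each model, so any stage can be reproduced in isolation.

## Problem sizes

The default study simulates 15 subjects (≈600–800 s of 19-channel
signal each), trains on 720 trials (4 × 90 targets + matched
non-targets; with the deposited real recordings this would be the
366 + 366 assembly) and evaluates on 11 × 180 balanced trials; a full
run takes under a minute on one CPU core. The test suite runs the full
study three times (strong-response twice for the bit-identical rerun
check, zero-amplitude once).

## Known limitations

- The sigmoid/full-batch optimizer is faithful to the from-scratch
  design goal, not to modern deep-learning practice; it is adequate at
  these scales but would not scale to large corpora.
- The simulator's stationarity and fixed topography make the synthetic
  task markedly easier than real cross-subject P300 detection; see the
  simulator caveats above.
- BrainVision writing covers only the INT_16 multiplexed dialect;
  reading supports what MNE supports.
- The McNemar exact/asymptotic switch at 25 discordant pairs is a
  convention; results near the boundary can differ slightly between
  the two branches.
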