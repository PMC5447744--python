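"""Synthetic oddball-paradigm EEG sessions with embedded P300 responses.

The simulator emulates a three-stimulus oddball recording: stimuli are
delivered at a fixed 1 Hz rate with configurable target / non-target /
distractor probabilities (13.5 / 83 / 3.5 % by default), a session runs
in phases that each continue until a quota of target stimuli has been
reached, and each target stimulus adds a smooth positive deflection --
a Gaussian bump with centro-parietal topography peaking a few hundred
milliseconds post-stimulus -- on top of stochastic background EEG
(pink noise + alpha rhythm + white noise).

All randomness flows through seeded NumPy generators; a session spawns
independent substreams for the stimulus sequence, the background and the
event responses, so the same seed yields the same background regardless
of the subject's response profile (superposition is exact).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from p300sae.io import (
    DISTRACTOR_CODE,
    NONTARGET_CODE,
    TARGET_CODE,
    ContinuousRecording,
)

logger = logging.getLogger(__name__)

#: Standard 10-20 labels of the 19-channel montage the simulator emulates.
CHANNELS_19 = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
]

# Relative P300 gain per channel; centro-parietal emphasis, max 1 at Pz.
_P300_GAINS = {
    "Pz": 1.0, "Cz": 0.9, "P3": 0.85, "P4": 0.85, "C3": 0.7, "C4": 0.7,
    "Fz": 0.55, "O1": 0.5, "O2": 0.5, "T5": 0.45, "T6": 0.45,
}
# Frontal emphasis for the distractor (P3a-like) response, max 1 at Fz.
_P3A_GAINS = {
    "Fz": 1.0, "Cz": 0.85, "F3": 0.8, "F4": 0.8, "Fp1": 0.6, "Fp2": 0.6,
    "F7": 0.5, "F8": 0.5, "Pz": 0.4,
}
_DEFAULT_GAIN = 0.3


def _as_generator(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class NoiseModel:
    """Background-EEG noise descriptor (amplitudes in microvolts).

    ``pink_sd`` sets the standard deviation of the 1/f^exponent component,
    ``alpha_amplitude`` the peak amplitude of a sinusoidal alpha rhythm
    with random per-channel phase, and ``white_sd`` the standard deviation
    of additive white noise.
    """

    pink_exponent: float = 1.0
    pink_sd: float = 4.0
    alpha_amplitude: float = 2.0
    alpha_frequency: float = 10.0
    white_sd: float = 1.0

    def __post_init__(self) -> None:
        if min(self.pink_sd, self.alpha_amplitude, self.white_sd) < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.alpha_frequency <= 0:
            raise ValueError("alpha_frequency must be positive")


@dataclass
class SimulationConfig:
    """Recording and stimulation-protocol parameters.

    Defaults follow a 19-channel, 1 kHz oddball protocol: one 500 ms
    flash per second with non-target / target / distractor probabilities
    0.83 / 0.135 / 0.035, three phases of 30 target stimuli each.
    """

    n_channels: int = 19
    sampling_rate: float = 1000.0
    stim_interval: float = 1.0
    stim_duration: float = 0.5  # informational; flash length, not used in synthesis
    p_nontarget: float = 0.83
    p_target: float = 0.135
    p_distractor: float = 0.035
    n_phases: int = 3
    targets_per_phase: int = 30
    noise: NoiseModel = field(default_factory=NoiseModel)
    target_code: str = TARGET_CODE
    nontarget_code: str = NONTARGET_CODE
    distractor_code: str = DISTRACTOR_CODE
    seed: int | None = None

    def __post_init__(self) -> None:
        total = self.p_nontarget + self.p_target + self.p_distractor
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"stimulus probabilities sum to {total}, not 1")
        if min(self.p_nontarget, self.p_target, self.p_distractor) < 0:
            raise ValueError("stimulus probabilities must be non-negative")
        if self.n_channels < 1 or self.n_phases < 1 or self.targets_per_phase < 1:
            raise ValueError("counts must be strictly positive")
        if self.sampling_rate <= 0 or self.stim_interval <= 0:
            raise ValueError("sampling_rate and stim_interval must be positive")

    @property
    def channel_labels(self) -> list[str]:
        if self.n_channels == len(CHANNELS_19):
            return list(CHANNELS_19)
        return [f"ch{i:02d}" for i in range(self.n_channels)]

    @property
    def stim_spacing(self) -> int:
        """Inter-stimulus spacing in samples."""
        return int(round(self.stim_interval * self.sampling_rate))


def default_topography(channel_labels: Sequence[str], gains: dict[str, float] | None = None) -> np.ndarray:
    """Per-channel gain vector in [0, 1] with centro-parietal emphasis."""
    gains = _P300_GAINS if gains is None else gains
    topo = np.array([gains.get(c, _DEFAULT_GAIN) for c in channel_labels], dtype=float)
    return topo / topo.max()


@dataclass
class DistractorResponse:
    """Optional P3a-like response to distractor stimuli: an earlier,
    frontally distributed positivity."""

    amplitude: float = 3.0
    latency: float = 300.0
    width: float = 50.0


@dataclass
class SubjectProfile:
    """Per-subject P300 response parameters.

    ``p300_amplitude`` is the mean peak height in microvolts at the
    maximum-gain channel, ``p300_latency`` the mean peak time in ms
    post-stimulus, ``latency_jitter`` its trial-to-trial standard
    deviation in ms, and ``p300_width`` the Gaussian temporal spread
    (standard deviation) in ms.
    """

    p300_amplitude: float = 5.0
    p300_latency: float = 400.0
    latency_jitter: float = 30.0
    p300_width: float = 60.0
    topography: np.ndarray | None = None
    distractor_response: DistractorResponse | None = None
    subject_id: str | None = None

    def resolved_topography(self, config: SimulationConfig) -> np.ndarray:
        if self.topography is not None:
            topo = np.asarray(self.topography, dtype=float)
            if len(topo) != config.n_channels:
                raise ValueError(
                    f"topography has {len(topo)} entries for {config.n_channels} channels"
                )
            if not math.isclose(topo.max(), 1.0, rel_tol=1e-9):
                raise ValueError("topography max entry must be 1")
            return topo
        return default_topography(config.channel_labels)


class StimulusEvent(NamedTuple):
    onset_sample: int
    code: str


def generate_stimulus_sequence(
    config: SimulationConfig,
    n_events: int,
    rng: np.random.Generator | int | None = None,
) -> list[StimulusEvent]:
    """Draw an i.i.d. stimulus sequence at the fixed stimulation rate.

    Events are spaced exactly ``stim_interval`` apart, starting one
    interval into the recording; codes are drawn independently with the
    configured non-target / target / distractor probabilities.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = _as_generator(rng)
    codes = (config.nontarget_code, config.target_code, config.distractor_code)
    probs = (config.p_nontarget, config.p_target, config.p_distractor)
    draws = rng.choice(3, size=n_events, p=probs)
    spacing = config.stim_spacing
    return [StimulusEvent(spacing * (i + 1), codes[d]) for i, d in enumerate(draws)]


def _pink_noise(n_samples: int, exponent: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise, scaled to sd."""
    from scipy.fft import irfft, next_fast_len, rfft

    n_fft = next_fast_len(n_samples)  # pad: awkward lengths make the FFT crawl
    white = rng.standard_normal(n_fft)
    spec = rfft(white)
    freqs = np.fft.rfftfreq(n_fft)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)  # DC removed
    x = irfft(spec * scale, n_fft)[:n_samples]
    x -= x.mean()
    s = x.std()
    return x * (sd / s) if s > 0 else x


def generate_background(
    config: SimulationConfig,
    n_samples: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Zero-mean background EEG: pink noise + alpha rhythm + white noise.

    Returns an array of shape ``(n_channels, n_samples)`` in microvolts.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = _as_generator(rng)
    nm = config.noise
    t = np.arange(n_samples) / config.sampling_rate
    signal = np.zeros((config.n_channels, n_samples))
    for c in range(config.n_channels):
        if nm.pink_sd > 0:
            signal[c] += _pink_noise(n_samples, nm.pink_exponent, nm.pink_sd, rng)
        if nm.alpha_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            signal[c] += nm.alpha_amplitude * np.sin(2 * np.pi * nm.alpha_frequency * t + phase)
        if nm.white_sd > 0:
            signal[c] += rng.normal(0.0, nm.white_sd, n_samples)
    return signal


def generate_event_response(
    profile: SubjectProfile,
    code: str,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Additive multi-channel waveform for one stimulus.

    Target stimuli produce a Gaussian bump of the profile's amplitude at
    its latency (plus Gaussian jitter), scaled per channel by the
    topography; non-targets produce a zero waveform; distractors produce
    an optional earlier frontal positivity if the profile enables one.
    The waveform covers 1000 ms post-stimulus.
    """
    valid = {config.target_code, config.nontarget_code, config.distractor_code}
    if code not in valid:
        raise ValueError(f"unknown stimulus code {code!r}")
    rng = _as_generator(rng)
    fs = config.sampling_rate
    n = int(round(fs))  # 1000 ms
    out = np.zeros((config.n_channels, n))
    if code == config.nontarget_code:
        return out
    if code == config.target_code:
        amp, lat0, width = profile.p300_amplitude, profile.p300_latency, profile.p300_width
        jitter = profile.latency_jitter
        topo = profile.resolved_topography(config)
    else:  # distractor
        if profile.distractor_response is None:
            return out
        d = profile.distractor_response
        amp, lat0, width = d.amplitude, d.latency, d.width
        jitter = profile.latency_jitter
        topo = default_topography(config.channel_labels, _P3A_GAINS)
    lat = lat0 + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
    t_ms = np.arange(n) * 1000.0 / fs
    bump = amp * np.exp(-0.5 * ((t_ms - lat) / width) ** 2)
    out[:] = topo[:, None] * bump[None, :]
    return out


def simulate_session(
    config: SimulationConfig,
    profile: SubjectProfile,
    rng: np.random.Generator | int | None = None,
) -> ContinuousRecording:
    """Simulate one continuous oddball session.

    Each of the ``n_phases`` phases continues until ``targets_per_phase``
    target stimuli have occurred; phases are concatenated into a single
    continuous recording (phase boundaries recorded in metadata).  The
    signal is background EEG plus the superposed per-event responses;
    the marker track lists every stimulus, including distractors.
    """
    if rng is None:
        rng = config.seed
    root = _as_generator(rng)
    g_seq, g_bg, g_resp = root.spawn(3)

    codes = (config.nontarget_code, config.target_code, config.distractor_code)
    probs = (config.p_nontarget, config.p_target, config.p_distractor)
    spacing = config.stim_spacing
    markers: list[tuple[int, str]] = []
    phase_boundaries: list[int] = []
    onset = spacing
    for _ in range(config.n_phases):
        n_targets = 0
        while n_targets < config.targets_per_phase:
            code = codes[int(g_seq.choice(3, p=probs))]
            markers.append((onset, code))
            if code == config.target_code:
                n_targets += 1
            onset += spacing
        phase_boundaries.append(onset)

    n_samples = markers[-1][0] + int(round(1.5 * config.sampling_rate))
    signal = generate_background(config, n_samples, g_bg)
    for onset_s, code in markers:
        resp = generate_event_response(profile, code, config, g_resp)
        hi = min(onset_s + resp.shape[1], n_samples)
        signal[:, onset_s:hi] += resp[:, : hi - onset_s]

    return ContinuousRecording(
        signal=signal,
        sampling_rate=config.sampling_rate,
        channel_labels=config.channel_labels,
        markers=markers,
        metadata={
            "subject_id": profile.subject_id,
            "phase_boundaries": phase_boundaries,
            "p300_amplitude": profile.p300_amplitude,
            "p300_latency": profile.p300_latency,
        },
    )


def simulate_cohort(
    config: SimulationConfig,
    profiles: Sequence[SubjectProfile],
    rng: np.random.Generator | int | None = None,
) -> list[ContinuousRecording]:
    """One independent session per profile, with per-subject substreams
    derived deterministically from the master seed."""
    if not profiles:
        raise ValueError("need at least one subject profile")
    root = _as_generator(rng)
    children = root.spawn(len(profiles))
    return [simulate_session(config, p, g) for p, g in zip(profiles, children)]


def make_cohort_profiles(
    n_subjects: int,
    rng: np.random.Generator | int | None = None,
    amplitude_range: tuple[float, float] = (2.0, 10.0),
    latency: float = 400.0,
    latency_jitter: float = 30.0,
    width: float = 60.0,
    id_prefix: str = "S",
) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles with amplitudes uniform in
    ``amplitude_range`` (conventional single-trial P300 peak heights)."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = _as_generator(rng)
    amps = rng.uniform(*amplitude_range, size=n_subjects)
    return [
        SubjectProfile(
            p300_amplitude=float(a),
            p300_latency=latency,
            latency_jitter=latency_jitter,
            p300_width=width,
            subject_id=f"{id_prefix}{i + 1:02d}",
        )
        for i, a in enumerate(amps)
    ]
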