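"""Oddball-session simulator: stimulus statistics, noise model,
response shapes and determinism."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

from p300sae.simulate import (
    NoiseModel,
    SimulationConfig,
    SubjectProfile,
    generate_background,
    generate_event_response,
    generate_stimulus_sequence,
    make_cohort_profiles,
    simulate_cohort,
    simulate_session,
)
from p300sae.io import extract_epochs


class TestStimulusSequence:
    def test_code_frequencies_match_protocol_probabilities(self):
        cfg = SimulationConfig()
        seq = generate_stimulus_sequence(cfg, 100_000, rng=7)
        frac = np.mean([e.code == cfg.target_code for e in seq])
        sd = np.sqrt(0.135 * 0.865 / 100_000)
        assert abs(frac - 0.135) < 3 * sd

    def test_degenerate_distribution_all_targets(self):
        cfg = SimulationConfig(p_target=1.0, p_nontarget=0.0, p_distractor=0.0)
        seq = generate_stimulus_sequence(cfg, 10, rng=0)
        assert all(e.code == cfg.target_code for e in seq)

    def test_fixed_seed_reproducible(self):
        cfg = SimulationConfig()
        assert generate_stimulus_sequence(cfg, 500, rng=3) == generate_stimulus_sequence(cfg, 500, rng=3)

    def test_events_spaced_exactly_one_interval(self):
        cfg = SimulationConfig()
        seq = generate_stimulus_sequence(cfg, 50, rng=0)
        onsets = np.array([e.onset_sample for e in seq])
        assert np.all(np.diff(onsets) == cfg.stim_spacing)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            generate_stimulus_sequence(SimulationConfig(), 0, rng=0)

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_target=0.5, p_nontarget=0.5, p_distractor=0.1)


class TestBackground:
    def test_white_noise_sd_echoes_parameter(self):
        cfg = SimulationConfig(
            n_channels=2, noise=NoiseModel(pink_sd=0, alpha_amplitude=0, white_sd=1.0)
        )
        bg = generate_background(cfg, 100_000, rng=1)
        assert np.allclose(bg.std(axis=1), 1.0, rtol=0.05)

    def test_zero_amplitudes_give_silent_signal(self):
        cfg = SimulationConfig(noise=NoiseModel(pink_sd=0, alpha_amplitude=0, white_sd=0))
        assert not generate_background(cfg, 1000, rng=0).any()

    def test_pink_component_has_low_frequency_emphasis(self):
        cfg = SimulationConfig(
            n_channels=1, noise=NoiseModel(pink_sd=4.0, alpha_amplitude=0, white_sd=0)
        )
        bg = generate_background(cfg, 200_000, rng=2)
        freqs, psd = sps.welch(bg[0], fs=cfg.sampling_rate, nperseg=8192)
        p2 = psd[np.argmin(np.abs(freqs - 2.0))]
        p40 = psd[np.argmin(np.abs(freqs - 40.0))]
        assert p2 > p40


class TestEventResponse:
    def test_nontarget_response_is_zero(self):
        cfg = SimulationConfig()
        resp = generate_event_response(SubjectProfile(), cfg.nontarget_code, cfg, rng=0)
        assert not resp.any()

    def test_target_peak_equals_amplitude_at_latency(self):
        cfg = SimulationConfig()
        prof = SubjectProfile(p300_amplitude=7.0, p300_latency=400.0, latency_jitter=0.0)
        resp = generate_event_response(prof, cfg.target_code, cfg, rng=0)
        best = np.argmax(resp.max(axis=1))  # max-gain channel
        assert cfg.channel_labels[best] == "Pz"
        assert resp[best].max() == pytest.approx(7.0, rel=1e-9)
        assert np.argmax(resp[best]) == 400

    def test_latency_jitter_sd_recovered_by_monte_carlo(self, rng):
        cfg = SimulationConfig(n_channels=1)
        prof = SubjectProfile(
            p300_amplitude=5.0, latency_jitter=30.0, topography=np.array([1.0])
        )
        peaks = [
            np.argmax(generate_event_response(prof, cfg.target_code, cfg, rng)[0])
            for _ in range(1000)
        ]
        assert np.std(peaks) == pytest.approx(30.0, rel=0.12)

    def test_distractor_response_off_by_default(self):
        cfg = SimulationConfig()
        resp = generate_event_response(SubjectProfile(), cfg.distractor_code, cfg, rng=0)
        assert not resp.any()

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            generate_event_response(SubjectProfile(), "S 99", SimulationConfig(), rng=0)


class TestSession:
    def test_default_session_has_90_targets_30_per_phase(self):
        cfg = SimulationConfig()
        rec = simulate_session(cfg, SubjectProfile(), rng=5)
        targets = [on for on, c in rec.markers if c == cfg.target_code]
        assert len(targets) == 90
        boundaries = [0] + rec.metadata["phase_boundaries"]
        for lo, hi in zip(boundaries, boundaries[1:]):
            assert sum(1 for on in targets if lo <= on < hi) == 30

    def test_superposition_of_background_and_responses(self, quiet_config):
        """With jitter disabled, a session is exactly the background-only
        session (same seed) plus the deterministic response track."""
        cfg = quiet_config
        prof = SubjectProfile(p300_amplitude=6.0, latency_jitter=0.0, subject_id="a")
        prof0 = SubjectProfile(p300_amplitude=0.0, latency_jitter=0.0, subject_id="a")
        rec = simulate_session(cfg, prof, rng=11)
        rec0 = simulate_session(cfg, prof0, rng=11)
        assert rec.markers == rec0.markers
        diff = rec.signal - rec0.signal
        track = np.zeros_like(diff)
        resp = generate_event_response(prof, cfg.target_code, cfg, rng=0)
        for onset, code in rec.markers:
            if code == cfg.target_code:
                hi = min(onset + resp.shape[1], track.shape[1])
                track[:, onset:hi] += resp[:, : hi - onset]
        assert np.allclose(diff, track, atol=1e-10)

    def test_grand_average_extremum_within_latency_window(self, tiny_sim_config):
        prof = SubjectProfile(p300_amplitude=8.0, latency_jitter=10.0)
        rec = simulate_session(tiny_sim_config, prof, rng=21)
        es = extract_epochs(rec)
        diff = es.data[es.labels == 1].mean(axis=0) - es.data[es.labels == 0].mean(axis=0)
        pz = es.channel_labels.index("Pz")
        peak_ms = np.argmax(diff[pz]) - es.t0_offset
        assert abs(peak_ms - prof.p300_latency) <= prof.p300_width

    def test_zero_amplitude_targets_indistinguishable_from_nontargets(self, tiny_sim_config):
        prof = SubjectProfile(p300_amplitude=0.0)
        rec = simulate_session(tiny_sim_config, prof, rng=31)
        es = extract_epochs(rec)
        pz = es.channel_labels.index("Pz")
        win = slice(es.t0_offset + 350, es.t0_offset + 450)
        t_means = es.data[es.labels == 1, pz, win].mean(axis=1)
        n_means = es.data[es.labels == 0, pz, win].mean(axis=1)
        assert stats.ttest_ind(t_means, n_means).pvalue > 0.01


class TestCohort:
    def test_cohort_size_matches_study_design(self, tiny_sim_config):
        profiles = make_cohort_profiles(4, rng=0) + make_cohort_profiles(11, rng=1, id_prefix="T")
        recs = simulate_cohort(tiny_sim_config, profiles, rng=2)
        assert len(recs) == 15

    def test_same_master_seed_bitwise_identical(self, tiny_sim_config):
        profiles = make_cohort_profiles(2, rng=0)
        a = simulate_cohort(tiny_sim_config, profiles, rng=9)
        b = simulate_cohort(tiny_sim_config, profiles, rng=9)
        assert all(x == y for x, y in zip(a, b))

    def test_empty_profile_list_rejected(self, tiny_sim_config):
        with pytest.raises(ValueError):
            simulate_cohort(tiny_sim_config, [], rng=0)

    def test_profile_amplitudes_within_range(self):
        profiles = make_cohort_profiles(50, rng=3, amplitude_range=(2.0, 10.0))
        amps = [p.p300_amplitude for p in profiles]
        assert min(amps) >= 2.0 and max(amps) <= 10.0
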