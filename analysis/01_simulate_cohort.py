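#!/usr/bin/env python
"""Simulate the study cohort: 4 training + 11 testing subjects.

Each subject gets an independent oddball session (19 channels, 1 kHz,
three phases of 30 target stimuli) with a subject-specific P300
amplitude drawn from 2-10 uV.  Recordings are written as HDF5
containers under scratch/recordings/ and the study configuration is
saved so the later stages reproduce the exact same cohort.
"""

import argparse
import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from p300sae.config import StudyConfig, save_config
from p300sae.io import write_container
from p300sae.simulate import make_cohort_profiles, simulate_session

SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    config = StudyConfig(seed=args.seed)
    out_dir = os.path.join(SCRATCH, "recordings")
    os.makedirs(out_dir, exist_ok=True)
    save_config(config, os.path.join(SCRATCH, "config.yaml"))

    root = np.random.default_rng(config.seed)
    g_train_prof, g_test_prof, g_train_sim, g_test_sim = root.spawn(4)
    co = config.cohort
    groups = [
        ("train", make_cohort_profiles(co.n_train, g_train_prof, co.amplitude_range,
                                       co.latency, co.latency_jitter, co.width, id_prefix="train"),
         g_train_sim),
        ("test", make_cohort_profiles(co.n_test, g_test_prof, co.amplitude_range,
                                      co.latency, co.latency_jitter, co.width, id_prefix="test"),
         g_test_sim),
    ]
    for group, profiles, g_sim in groups:
        for profile, child in zip(profiles, g_sim.spawn(len(profiles))):
            rec = simulate_session(config.simulation, profile, child)
            n_targets = sum(1 for _, c in rec.markers if c == config.simulation.target_code)
            path = os.path.join(out_dir, f"{profile.subject_id}.h5")
            write_container(rec, path)
            print(
                f"{group:5s} {profile.subject_id}: amplitude {profile.p300_amplitude:4.1f} uV, "
                f"{len(rec.markers)} stimuli ({n_targets} targets), "
                f"{rec.n_samples / rec.sampling_rate:.0f} s"
            )
    print(f"\nrecordings and config written under {os.path.abspath(SCRATCH)}")


if __name__ == "__main__":
    main()
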