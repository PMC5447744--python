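#!/usr/bin/env python
"""Epoch every recording and extract windowed-means features.

Trials span -500..+1000 ms around target (S  2) and non-target (S  4)
markers; distractors are ignored.  After baseline correction, 11
consecutive 50 ms window means per channel (150-700 ms post-stimulus)
are concatenated over the 19 channels into 209-dimensional vectors and
length-normalized.  Per-subject epoch containers go to scratch/epochs/;
the per-subject balanced test sets are reduced here (all targets plus
the first equal number of non-targets).
"""

import glob
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from p300sae.config import load_config
from p300sae.features import extract_features
from p300sae.io import extract_epochs, read_container, save_epochs, select_test_trials

SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch")


def main() -> None:
    config = load_config(os.path.join(SCRATCH, "config.yaml"))
    fp, sc = config.features, config.simulation
    out_dir = os.path.join(SCRATCH, "epochs")
    os.makedirs(out_dir, exist_ok=True)

    for path in sorted(glob.glob(os.path.join(SCRATCH, "recordings", "*.h5"))):
        rec = read_container(path)
        subject = rec.metadata["subject_id"]
        epochs = extract_epochs(rec, sc.target_code, sc.nontarget_code, fp.pre_ms, fp.post_ms)
        if subject.startswith("test"):
            epochs = select_test_trials(epochs)
        save_epochs(epochs, os.path.join(out_dir, f"{subject}.h5"))
        fm = extract_features(epochs, fp.start_ms, fp.end_ms, fp.width_ms, fp.baseline_ms)
        print(
            f"{subject}: {epochs.n_trials} trials "
            f"({int(epochs.labels.sum())} targets) -> {fm.n_features} features"
        )
    print(f"\nepoch containers written under {os.path.join(os.path.abspath(SCRATCH), 'epochs')}")


if __name__ == "__main__":
    main()
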