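#!/usr/bin/env python
"""Assemble the merged training set and train the three classifiers.

Training pool: from each of the 4 training subjects, all target trials
plus an equal random subset of its non-targets, shuffled.  The stacked
sparse autoencoder (209-130-100-50-20-2) is greedily pretrained, topped
with a softmax head and fine-tuned; the MLP shares the architecture but
trains from random initialization; shrinkage LDA uses an analytically
chosen covariance shrinkage.  Networks use a 20% random validation
split for early stopping.  Models are saved under scratch/models/.
"""

import glob
import os
import sys
import time

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from p300sae.baselines import predict_lda, train_mlp, train_shrinkage_lda
from p300sae.config import load_config
from p300sae.features import extract_features
from p300sae.io import assemble_training_set, load_epochs, split_validation
from p300sae.sae import predict, save_model, train_sae

SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch")


def main() -> None:
    config = load_config(os.path.join(SCRATCH, "config.yaml"))
    fp = config.features
    root = np.random.default_rng(config.seed)
    g_assemble, g_split, g_models = root.spawn(3)

    train_sets = [
        load_epochs(p) for p in sorted(glob.glob(os.path.join(SCRATCH, "epochs", "train*.h5")))
    ]
    merged = assemble_training_set(train_sets, g_assemble)
    fm = extract_features(merged, fp.start_ms, fp.end_ms, fp.width_ms, fp.baseline_ms)
    tr, va = split_validation(fm, config.validation_fraction, g_split)
    print(
        f"training set: {fm.n_trials} trials ({int(fm.labels.sum())} targets), "
        f"split {tr.n_trials}/{va.n_trials} train/validation"
    )

    out_dir = os.path.join(SCRATCH, "models")
    os.makedirs(out_dir, exist_ok=True)
    for name in config.models:
        child = g_models.spawn(1)[0]
        t0 = time.time()
        if name == "lda":
            model = train_shrinkage_lda(fm.values, fm.labels)
            val_acc = np.mean(predict_lda(model, va.values)[0] == va.labels)
            note = f"shrinkage intensity {model.shrinkage_intensity:.3f}"
        elif name == "mlp":
            model = train_mlp(tr.values, tr.labels, tuple(config.sae.layer_sizes),
                              config.mlp_iterations, child, va.values, va.labels,
                              config.sae.learning_rate, config.sae.momentum)
            val_acc = np.mean(predict(model, va.values)[0] == va.labels)
            note = f"architecture {model.architecture}"
        else:
            model = train_sae(tr.values, tr.labels, config.sae, child, va.values, va.labels)
            val_acc = np.mean(predict(model, va.values)[0] == va.labels)
            note = f"architecture {model.architecture}"
        save_model(model, os.path.join(out_dir, f"{name}.h5"))
        print(f"{name}: validation accuracy {100 * val_acc:.1f}% ({note}, {time.time() - t0:.0f}s)")
    print(f"\nmodels written under {os.path.abspath(out_dir)}")


if __name__ == "__main__":
    main()
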