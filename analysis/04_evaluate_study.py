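#!/usr/bin/env python
"""Evaluate the frozen classifiers on the 11 test subjects.

Each test subject contributes a balanced set (~90 targets + the first
~90 non-targets); no weight updates happen at test time.  Writes
per-subject and average accuracy / precision / recall tables and the
pooled McNemar paired comparisons under results/.
"""

import glob
import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from p300sae.baselines import LdaModel, predict_lda
from p300sae.config import load_config
from p300sae.evaluation import MetricsReport, confusion, mcnemar, metrics
from p300sae.features import extract_features
from p300sae.io import load_epochs
from p300sae.sae import load_model, predict

SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch")
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    config = load_config(os.path.join(SCRATCH, "config.yaml"))
    fp = config.features
    models = {
        name: load_model(os.path.join(SCRATCH, "models", f"{name}.h5"))
        for name in config.models
    }

    rows, pooled, truth = [], {name: [] for name in models}, []
    for path in sorted(glob.glob(os.path.join(SCRATCH, "epochs", "test*.h5"))):
        epochs = load_epochs(path)
        fm = extract_features(epochs, fp.start_ms, fp.end_ms, fp.width_ms, fp.baseline_ms)
        truth.append(fm.labels)
        for name, model in models.items():
            preds = (
                predict_lda(model, fm.values)[0]
                if isinstance(model, LdaModel)
                else predict(model, fm.values)[0]
            )
            pooled[name].append(preds)
            counts = confusion(fm.labels, preds)
            acc, prec, rec = metrics(counts)
            rows.append({
                "repetition": 0, "subject": epochs.subject_id, "classifier": name,
                "tp": counts.tp, "tn": counts.tn, "fp": counts.fp, "fn": counts.fn,
                "accuracy": acc, "precision": prec, "recall": rec,
            })

    per_subject = pd.DataFrame(rows)
    averages = (per_subject.groupby("classifier", sort=False)[["accuracy", "precision", "recall"]]
                .mean().reset_index())
    y = np.concatenate(truth)
    names = list(models)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            res = mcnemar(np.concatenate(pooled[a]), np.concatenate(pooled[b]), y)
            pairs.append({"classifier_a": a, "classifier_b": b, "a_only_correct": res.b,
                          "b_only_correct": res.c, "p_value": res.p_value, "method": res.method})
    report = MetricsReport(per_subject, averages, pd.DataFrame(pairs),
                           meta={"seed": config.seed})
    report.save(RESULTS)
    print(report.summary())
    print(f"\ntables written under {os.path.abspath(RESULTS)}")


if __name__ == "__main__":
    main()
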