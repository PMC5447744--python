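"""Study evaluation: confusion metrics, McNemar tests, full pipeline.

Metrics follow the usual detection conventions with the target (P300
present) class positive:

    accuracy  = (tp + tn) / (tp + tn + fp + fn)
    precision = tp / (tp + fp)
    recall    = tp / (tp + fn)

all expressed in percent.  Paired classifiers are compared with the
McNemar test on their discordant predictions over the same trials:
exact two-sided binomial when the discordant count is small, otherwise
the chi-square approximation with continuity correction.

:func:`run_study` drives the whole experiment: simulate (or load) a
cohort, epoch, extract features, assemble a balanced multi-subject
training set, train the configured classifiers once, and evaluate them
on balanced per-subject test sets without any further weight updates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from p300sae import features as feat
from p300sae import io as pio
from p300sae import simulate as sim
from p300sae.baselines import predict_lda, train_mlp, train_shrinkage_lda
from p300sae.config import StudyConfig
from p300sae.sae import predict, train_sae

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """2x2 confusion counts with target = positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(true_labels: np.ndarray, predicted_labels: np.ndarray) -> ConfusionCounts:
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary (0 = nontarget, 1 = target)")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, precision, recall) in percent.

    An undefined ratio (zero denominator) is reported as NaN with a
    logged warning rather than raising.
    """
    if counts.n == 0:
        raise ValueError("all confusion counts are zero")
    accuracy = 100.0 * (counts.tp + counts.tn) / counts.n
    if counts.tp + counts.fp == 0:
        logger.warning("precision undefined (no positive predictions); reporting NaN")
        precision = float("nan")
    else:
        precision = 100.0 * counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        logger.warning("recall undefined (no positive trials); reporting NaN")
        recall = float("nan")
    else:
        recall = 100.0 * counts.tp / (counts.tp + counts.fn)
    return accuracy, precision, recall


@dataclass
class McNemarResult:
    b: int  # a correct, b wrong
    c: int  # a wrong, b correct
    p_value: float
    method: str


def mcnemar(
    preds_a: np.ndarray,
    preds_b: np.ndarray,
    true_labels: np.ndarray,
    exact_threshold: int = 25,
) -> McNemarResult:
    """Paired McNemar test on two classifiers' discordant trials.

    ``b`` counts trials classifier A got right and B wrong, ``c`` the
    reverse.  With fewer than ``exact_threshold`` discordant trials the
    two-sided exact binomial p-value is used; otherwise the chi-square
    statistic with continuity correction.  No discordance gives p = 1.
    """
    pa, pb, y = (np.asarray(v, dtype=int) for v in (preds_a, preds_b, true_labels))
    if not (pa.shape == pb.shape == y.shape):
        raise ValueError("prediction and label arrays must have equal length")
    a_ok, b_ok = pa == y, pb == y
    b = int(np.sum(a_ok & ~b_ok))
    c = int(np.sum(~a_ok & b_ok))
    n = b + c
    if n == 0:
        logger.info("mcnemar: no discordant trials, p = 1")
        return McNemarResult(b, c, 1.0, "degenerate")
    if n < exact_threshold:
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5))
        return McNemarResult(b, c, float(p), "exact-binomial")
    chi2 = (abs(b - c) - 1.0) ** 2 / n
    return McNemarResult(b, c, float(stats.chi2.sf(chi2, 1)), "chi-square")


@dataclass
class MetricsReport:
    """Study outcome: per-subject and averaged metrics per classifier,
    plus paired McNemar comparisons."""

    per_subject: pd.DataFrame
    averages: pd.DataFrame
    mcnemar_table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Average classification performance", "-" * 50]
        lines.append(self.averages.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
        if len(self.mcnemar_table):
            lines.append("")
            lines.append("McNemar paired comparisons (pooled test trials)")
            lines.append(
                self.mcnemar_table.to_string(index=False, float_format=lambda v: f"{v:.4g}")
            )
        return "\n".join(lines)

    def save(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        self.per_subject.to_csv(os.path.join(directory, "per_subject_metrics.csv"), index=False)
        self.averages.to_csv(os.path.join(directory, "average_metrics.csv"), index=False)
        self.mcnemar_table.to_csv(os.path.join(directory, "mcnemar.csv"), index=False)
        with open(os.path.join(directory, "summary.txt"), "w") as f:
            f.write(self.summary() + "\n")


def _pipeline_features(epochs: pio.EpochSet, fp) -> feat.FeatureMatrix:
    return feat.extract_features(
        epochs, start_ms=fp.start_ms, end_ms=fp.end_ms, width_ms=fp.width_ms, baseline_ms=fp.baseline_ms
    )


def _load_or_simulate(config: StudyConfig, root: np.random.Generator):
    """Yield (train_epoch_sets, test_epoch_sets) per the config source."""
    fp = config.features
    sc = config.simulation

    def epochs_of(rec):
        return pio.extract_epochs(
            rec,
            target_code=sc.target_code,
            nontarget_code=sc.nontarget_code,
            pre_ms=fp.pre_ms,
            post_ms=fp.post_ms,
        )

    if config.train_files or config.test_files:
        if not (config.train_files and config.test_files):
            raise ValueError("train_files and test_files must both be given for file-based studies")
        overlap = set(config.train_files) & set(config.test_files)
        if overlap:
            raise ValueError(f"training and testing subject lists overlap: {sorted(overlap)}")

        def load(path):
            rec = (
                pio.read_brainvision(path)
                if str(path).endswith(".vhdr")
                else pio.read_container(path)
            )
            rec.metadata.setdefault("subject_id", str(path))
            return epochs_of(rec)

        return [load(p) for p in config.train_files], [load(p) for p in config.test_files]

    g_train_prof, g_test_prof, g_train_sim, g_test_sim = root.spawn(4)
    co = config.cohort
    train_profiles = sim.make_cohort_profiles(
        co.n_train, g_train_prof, co.amplitude_range, co.latency, co.latency_jitter, co.width,
        id_prefix="train",
    )
    test_profiles = sim.make_cohort_profiles(
        co.n_test, g_test_prof, co.amplitude_range, co.latency, co.latency_jitter, co.width,
        id_prefix="test",
    )
    overlap = {p.subject_id for p in train_profiles} & {p.subject_id for p in test_profiles}
    if overlap:
        raise ValueError(f"training and testing subject lists overlap: {sorted(overlap)}")

    # simulate one session at a time and keep only the epochs
    train_sets = [
        epochs_of(sim.simulate_session(config.simulation, p, g))
        for p, g in zip(train_profiles, g_train_sim.spawn(co.n_train))
    ]
    test_sets = [
        epochs_of(sim.simulate_session(config.simulation, p, g))
        for p, g in zip(test_profiles, g_test_sim.spawn(co.n_test))
    ]
    return train_sets, test_sets


def _train_models(config: StudyConfig, train_fm, tr_part, val_part, rng):
    models = {}
    for name in config.models:
        child = rng.spawn(1)[0]
        if name == "lda":
            models[name] = train_shrinkage_lda(train_fm.values, train_fm.labels)
        elif name == "mlp":
            models[name] = train_mlp(
                tr_part.values,
                tr_part.labels,
                layer_sizes=tuple(config.sae.layer_sizes),
                iterations=config.mlp_iterations,
                rng=child,
                X_val=val_part.values,
                labels_val=val_part.labels,
                learning_rate=config.sae.learning_rate,
                momentum=config.sae.momentum,
            )
        elif name == "sae":
            models[name] = train_sae(
                tr_part.values,
                tr_part.labels,
                hyper=config.sae,
                rng=child,
                X_val=val_part.values,
                labels_val=val_part.labels,
            )
        else:
            raise ValueError(f"unknown model {name!r}")
    return models


def _predict(name: str, model, X: np.ndarray) -> np.ndarray:
    if name == "lda":
        return predict_lda(model, X)[0]
    return predict(model, X)[0]


def run_study(config: StudyConfig) -> MetricsReport:
    """Run the full study once and return the metrics report.

    The classifiers are trained a single time on the merged training
    set; test-set evaluation applies them frozen (no weight updates).
    With ``repetitions > 1`` training is repeated with fresh seeds and
    per-subject metrics are averaged (a model-selection aid); the
    McNemar comparison always uses the first trained instance.
    """
    root = np.random.default_rng(config.seed)
    g_data, g_assemble, g_split, g_models = root.spawn(4)

    train_sets, test_sets = _load_or_simulate(config, g_data)
    train_epochs = pio.assemble_training_set(train_sets, g_assemble)
    del train_sets
    train_fm = _pipeline_features(train_epochs, config.features)
    tr_part, val_part = pio.split_validation(train_fm, config.validation_fraction, g_split)

    test_fms = []
    for es in test_sets:
        balanced = pio.select_test_trials(es)
        test_fms.append((es.subject_id, _pipeline_features(balanced, config.features)))
    del test_sets

    rows = []
    first_pooled: dict[str, np.ndarray] = {}
    pooled_truth: np.ndarray | None = None
    for rep in range(max(1, config.repetitions)):
        models = _train_models(config, train_fm, tr_part, val_part, g_models)
        pooled: dict[str, list[np.ndarray]] = {m: [] for m in config.models}
        truth = []
        for subject_id, fm in test_fms:
            truth.append(fm.labels)
            for name, model in models.items():
                preds = _predict(name, model, fm.values)
                pooled[name].append(preds)
                counts = confusion(fm.labels, preds)
                acc, prec, rec = metrics(counts)
                rows.append(
                    {
                        "repetition": rep,
                        "subject": subject_id,
                        "classifier": name,
                        "tp": counts.tp,
                        "tn": counts.tn,
                        "fp": counts.fp,
                        "fn": counts.fn,
                        "accuracy": acc,
                        "precision": prec,
                        "recall": rec,
                    }
                )
        if rep == 0:
            first_pooled = {m: np.concatenate(v) for m, v in pooled.items()}
            pooled_truth = np.concatenate(truth)

    per_subject = pd.DataFrame(rows)
    averages = (
        per_subject.groupby("classifier", sort=False)[["accuracy", "precision", "recall"]]
        .mean()
        .reset_index()
    )

    pairs = []
    names = list(config.models)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            res = mcnemar(first_pooled[a], first_pooled[b], pooled_truth)
            pairs.append(
                {
                    "classifier_a": a,
                    "classifier_b": b,
                    "a_only_correct": res.b,
                    "b_only_correct": res.c,
                    "p_value": res.p_value,
                    "method": res.method,
                }
            )
    mcnemar_table = pd.DataFrame(
        pairs,
        columns=["classifier_a", "classifier_b", "a_only_correct", "b_only_correct", "p_value", "method"],
    )

    meta = {
        "seed": config.seed,
        "models": list(config.models),
        "n_train_subjects": config.cohort.n_train,
        "n_test_subjects": config.cohort.n_test,
        "n_training_trials": int(train_fm.n_trials),
        "n_features": int(train_fm.n_features),
    }
    return MetricsReport(per_subject=per_subject, averages=averages, mcnemar_table=mcnemar_table, meta=meta)
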