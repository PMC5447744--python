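"""Comparison classifiers: MLP with the SAE architecture, shrinkage LDA.

The MLP uses the same layer sizes, transfer functions, forward pass and
optimizer as the stacked autoencoder but skips unsupervised
pretraining: a randomly initialized network is trained jointly by
backpropagation (1000 iterations by default).

The LDA baseline shrinks the pooled within-class covariance toward a
scaled identity with an analytically chosen intensity (the Ledoit-Wolf
estimator), keeping the discriminant well-conditioned when the feature
dimensionality (209) is comparable to the training-set size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from p300sae.sae import SAEHyperparams, StackedNetwork, fine_tune, initialize_network, FeatureScaler


def train_mlp(
    X: np.ndarray,
    labels: np.ndarray,
    layer_sizes: tuple[int, ...] = (130, 100, 50, 20),
    iterations: int = 1000,
    rng: np.random.Generator | int | None = None,
    X_val: np.ndarray | None = None,
    labels_val: np.ndarray | None = None,
    learning_rate: float = 0.1,
    momentum: float = 0.9,
) -> StackedNetwork:
    """Backpropagation-only network with the stacked model's layout.

    Shares the forward pass and :func:`p300sae.sae.predict` with the
    stacked autoencoder; the only differences are random initialization
    in place of pretraining and the iteration budget.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    scaler = FeatureScaler.fit(X)
    net = initialize_network(X.shape[1], tuple(layer_sizes), 2, rng, scaler)
    hyper = SAEHyperparams(
        layer_sizes=tuple(layer_sizes),
        finetune_iterations=iterations,
        learning_rate=learning_rate,
        momentum=momentum,
    )
    net = fine_tune(net, X, labels, hyper, X_val=X_val, labels_val=labels_val)
    net.meta["model"] = "mlp"
    return net


@dataclass(eq=False)
class LdaModel:
    """Linear discriminant: labels follow sign(w . x - threshold), with
    the positive side the target class."""

    weight_vector: np.ndarray
    threshold: float
    shrinkage_intensity: float
    class_means: np.ndarray  # row 0: nontarget, row 1: target

    @property
    def n_features(self) -> int:
        return len(self.weight_vector)


def ledoit_wolf_intensity(Xc: np.ndarray) -> float:
    """Analytic shrinkage intensity for centered data rows ``Xc``.

    Shrinks the empirical covariance ``S = Xc' Xc / n`` toward
    ``nu * I`` with ``nu = trace(S) / d``; the optimal intensity is the
    ratio of the estimation variance of S to its total dispersion
    around the target, clipped to [0, 1].
    """
    n, d = Xc.shape
    S = Xc.T @ Xc / n
    nu = np.trace(S) / d
    d2 = np.sum((S - nu * np.eye(d)) ** 2)
    if d2 <= 0:
        return 0.0
    sq_norms = np.sum(Xc**2, axis=1)
    b2 = (np.sum(sq_norms**2) - n * np.sum(S**2)) / n**2
    return float(np.clip(min(b2, d2) / d2, 0.0, 1.0))


def train_shrinkage_lda(
    X: np.ndarray,
    labels: np.ndarray,
    shrinkage: float | None = None,
) -> LdaModel:
    """Fit LDA with the pooled covariance shrunk toward scaled identity.

    ``shrinkage=None`` selects the intensity analytically; passing a
    value in [0, 1] forces it (0 reproduces classical LDA, 1 the
    mean-difference classifier).  The decision threshold sits at the
    projected midpoint of the class means, appropriate for balanced
    classes.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    idx0, idx1 = np.flatnonzero(labels == 0), np.flatnonzero(labels == 1)
    if len(idx0) < 2 or len(idx1) < 2:
        raise ValueError("both classes must be present with at least 2 samples each")
    m0, m1 = X[idx0].mean(axis=0), X[idx1].mean(axis=0)
    Xc = X.astype(float).copy()
    Xc[idx0] -= m0
    Xc[idx1] -= m1

    lam = ledoit_wolf_intensity(Xc) if shrinkage is None else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage intensity must be in [0, 1]")
    n, d = Xc.shape
    S = Xc.T @ Xc / n
    nu = np.trace(S) / d
    S_shrunk = (1.0 - lam) * S + lam * nu * np.eye(d)

    w = linalg.solve(S_shrunk, m1 - m0, assume_a="pos")
    threshold = float(w @ (m0 + m1) / 2.0)
    return LdaModel(
        weight_vector=w,
        threshold=threshold,
        shrinkage_intensity=lam,
        class_means=np.stack([m0, m1]),
    )


def predict_lda(model: LdaModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and decision values; a trial exactly on the boundary is
    assigned to the non-target class."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(f"input has shape {X.shape}, model expects {model.n_features} columns")
    scores = X @ model.weight_vector - model.threshold
    return (scores > 0).astype(np.int8), scores
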