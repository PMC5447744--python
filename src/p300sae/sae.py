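"""From-scratch stacked sparse autoencoder with softmax head.

An autoencoder here is the classical two-stage approximation of the
identity: a logistic-sigmoid encoding layer of lower dimensionality than
the input, followed by a sigmoid decoding layer back to input size.  The
pretraining objective is

    J = MSE(x, x_hat) + (lambda/2) * ||W||^2 + beta * sum_j KL(rho || rho_hat_j)

where ``rho_hat_j`` is the batch-mean activation of hidden unit j and
KL is the Bernoulli Kullback-Leibler divergence, so hidden units are
pushed toward a target mean activation ``rho``.  Defaults mirror common
sparse-autoencoder toolbox settings: lambda = 0.004, beta = 4,
rho = 0.2, at most 200 pretraining epochs.

Stacking is greedy: each autoencoder is trained on the previous layer's
encodings; a softmax classifier is trained on the deepest code, and the
assembled network (209-130-100-50-20-2 at study defaults) is fine-tuned
end-to-end by backpropagation on the cross-entropy loss.

All optimization is deterministic full-batch gradient descent with
momentum and an adaptive step (growth on improvement, halving with
momentum reset on a cost increase), so results are reproducible from a
seed alone.  Because the decoder's sigmoid output lives in (0, 1), each
feature column is affinely mapped to [0.1, 0.9] before the first
autoencoder; the mapping is stored in the network and re-applied at
inference.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

_RHO_CLAMP = 1e-6


@dataclass
class SAEHyperparams:
    """Hyperparameters of the stacked sparse autoencoder.

    ``layer_sizes`` are the hidden sizes of the successive autoencoders;
    ``l2_weight`` (lambda), ``sparsity_weight`` (beta) and
    ``sparsity_target`` (rho) parameterize the pretraining objective.
    """

    layer_sizes: tuple[int, ...] = (130, 100, 50, 20)
    l2_weight: float = 0.004
    sparsity_weight: float = 4.0
    sparsity_target: float = 0.2
    max_pretrain_epochs: int = 200
    softmax_iterations: int = 200
    finetune_iterations: int = 200
    learning_rate: float = 0.1
    momentum: float = 0.9
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.sparsity_target < 1:
            raise ValueError("sparsity_target must be in (0, 1)")
        if self.l2_weight < 0 or self.sparsity_weight < 0:
            raise ValueError("l2_weight and sparsity_weight must be >= 0")
        if min(self.layer_sizes) < 1:
            raise ValueError("layer sizes must be positive")
        for name in ("max_pretrain_epochs", "softmax_iterations", "finetune_iterations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.learning_rate <= 0 or not 0 <= self.momentum < 1:
            raise ValueError("invalid optimizer settings")


@dataclass(eq=False)
class AutoencoderLayer:
    """One autoencoder: sigmoid encode and decode halves.

    ``encode_weights`` is (hidden x input); ``decode_weights`` is
    (input x hidden), so decoding returns to input dimensionality.
    """

    encode_weights: np.ndarray
    encode_bias: np.ndarray
    decode_weights: np.ndarray
    decode_bias: np.ndarray
    transfer: str = "logistic"

    @property
    def input_size(self) -> int:
        return self.encode_weights.shape[1]

    @property
    def hidden_size(self) -> int:
        return self.encode_weights.shape[0]


@dataclass(eq=False)
class FeatureScaler:
    """Per-column affine map onto [lo, hi], stored for inference.

    Constant columns map to the interval midpoint.
    """

    col_min: np.ndarray
    col_max: np.ndarray
    lo: float = 0.1
    hi: float = 0.9

    @classmethod
    def fit(cls, X: np.ndarray, lo: float = 0.1, hi: float = 0.9) -> "FeatureScaler":
        return cls(col_min=X.min(axis=0), col_max=X.max(axis=0), lo=lo, hi=hi)

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.col_max - self.col_min
        safe = np.where(span == 0, 1.0, span)
        out = self.lo + (self.hi - self.lo) * (X - self.col_min) / safe
        mid = 0.5 * (self.lo + self.hi)
        return np.where(span == 0, mid, out)


@dataclass(eq=False)
class StackedNetwork:
    """Encoder stack + softmax head; all learned parameters of the model."""

    layers: list[AutoencoderLayer]
    softmax_weights: np.ndarray
    softmax_bias: np.ndarray
    scaler: FeatureScaler | None = None
    meta: dict = field(default_factory=dict)

    @property
    def input_size(self) -> int:
        return self.layers[0].input_size if self.layers else self.softmax_weights.shape[1]

    @property
    def architecture(self) -> str:
        sizes = [self.input_size] + [l.hidden_size for l in self.layers]
        sizes.append(self.softmax_weights.shape[0])
        return "-".join(str(s) for s in sizes)

    def copy(self) -> "StackedNetwork":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Costs and gradients
# ---------------------------------------------------------------------------

def ae_cost_and_gradient(
    layer: AutoencoderLayer,
    X: np.ndarray,
    hyper: SAEHyperparams,
) -> tuple[float, dict[str, np.ndarray]]:
    """Sparse-autoencoder cost and exact analytic gradients.

    Cost = mean squared reconstruction error over all matrix elements
    + (lambda/2) * sum of squared encode+decode weights
    + beta * sum_j KL(rho || rho_hat_j).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("batch must be a non-empty 2-D array")
    if X.shape[1] != layer.input_size:
        raise ValueError(f"batch has {X.shape[1]} columns, layer expects {layer.input_size}")
    n, d = X.shape
    lam, beta, rho = hyper.l2_weight, hyper.sparsity_weight, hyper.sparsity_target

    H = expit(X @ layer.encode_weights.T + layer.encode_bias)
    Xhat = expit(H @ layer.decode_weights.T + layer.decode_bias)

    rho_hat = H.mean(axis=0)
    clipped = np.clip(rho_hat, _RHO_CLAMP, 1.0 - _RHO_CLAMP)
    if np.any(clipped != rho_hat):
        logger.warning("ae_cost: mean activations clamped to keep KL finite")
    rho_hat = clipped

    mse = np.mean((Xhat - X) ** 2)
    l2 = 0.5 * lam * (np.sum(layer.encode_weights**2) + np.sum(layer.decode_weights**2))
    kl = rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat))
    cost = mse + l2 + beta * np.sum(kl)

    # backprop
    d_out = 2.0 * (Xhat - X) / (n * d) * Xhat * (1 - Xhat)
    g_dec_w = d_out.T @ H + lam * layer.decode_weights
    g_dec_b = d_out.sum(axis=0)
    kl_grad = (-rho / rho_hat + (1 - rho) / (1 - rho_hat)) / n
    d_hid = (d_out @ layer.decode_weights + beta * kl_grad) * H * (1 - H)
    g_enc_w = d_hid.T @ X + lam * layer.encode_weights
    g_enc_b = d_hid.sum(axis=0)

    grads = {
        "encode_weights": g_enc_w,
        "encode_bias": g_enc_b,
        "decode_weights": g_dec_w,
        "decode_bias": g_dec_b,
    }
    return float(cost), grads


def softmax_probabilities(H: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    Z = H @ W.T + b
    Z -= Z.max(axis=1, keepdims=True)
    P = np.exp(Z)
    P /= P.sum(axis=1, keepdims=True)
    return P


def softmax_cost_and_gradient(
    W: np.ndarray, b: np.ndarray, H: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy of a softmax layer and its exact gradients."""
    n = H.shape[0]
    P = softmax_probabilities(H, W, b)
    eps = np.finfo(float).tiny
    cost = -np.mean(np.log(P[np.arange(n), labels] + eps))
    Y = np.zeros_like(P)
    Y[np.arange(n), labels] = 1.0
    dZ = (P - Y) / n
    return float(cost), dZ.T @ H, dZ.sum(axis=0)


# ---------------------------------------------------------------------------
# Deterministic full-batch optimizer
# ---------------------------------------------------------------------------

def _flatten(arrays: list[np.ndarray]) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    shapes = [a.shape for a in arrays]
    return np.concatenate([a.ravel() for a in arrays]), shapes


def _unflatten(vec: np.ndarray, shapes: list[tuple[int, ...]]) -> list[np.ndarray]:
    out, i = [], 0
    for s in shapes:
        size = int(np.prod(s))
        out.append(vec[i : i + size].reshape(s))
        i += size
    return out


def gradient_descent(
    fun,
    x0: np.ndarray,
    n_iter: int,
    learning_rate: float = 0.1,
    momentum: float = 0.9,
    callback=None,
) -> tuple[np.ndarray, float]:
    """Full-batch gradient descent with momentum and adaptive step.

    A step that increases the cost is rejected: the iterate is kept, the
    step size halved and the momentum reset.  Accepted steps grow the
    step by 5 % (capped at 100x the initial rate).  Exactly one
    cost/gradient evaluation per iteration; the final cost never exceeds
    the initial cost.
    """
    x = x0.copy()
    f, g = fun(x)
    lr, v = learning_rate, np.zeros_like(x)
    lr_max = 100.0 * learning_rate
    for it in range(n_iter):
        v = momentum * v - lr * g
        x_new = x + v
        f_new, g_new = fun(x_new)
        if f_new <= f:
            x, f, g = x_new, f_new, g_new
            lr = min(lr * 1.05, lr_max)
            if callback is not None:
                callback(it, x, f)
        else:
            lr *= 0.5
            v[:] = 0.0
    return x, f


def _init_matrix(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    fan_out, fan_in = shape
    r = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-r, r, size=shape)


def _init_layer(input_size: int, hidden_size: int, rng: np.random.Generator) -> AutoencoderLayer:
    return AutoencoderLayer(
        encode_weights=_init_matrix((hidden_size, input_size), rng),
        encode_bias=np.zeros(hidden_size),
        decode_weights=_init_matrix((input_size, hidden_size), rng),
        decode_bias=np.zeros(input_size),
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def encode(layer: AutoencoderLayer, X: np.ndarray) -> np.ndarray:
    """Sigmoid encoding; rows map into (0, 1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != layer.input_size:
        raise ValueError(f"input has shape {X.shape}, layer expects {layer.input_size} columns")
    return expit(X @ layer.encode_weights.T + layer.encode_bias)


def train_autoencoder(
    X: np.ndarray,
    hidden_size: int,
    hyper: SAEHyperparams,
    rng: np.random.Generator | int | None = None,
) -> AutoencoderLayer:
    """Train one sparse autoencoder by full-batch gradient descent."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if hidden_size >= X.shape[1]:
        raise ValueError(
            f"hidden size {hidden_size} must be below input dimensionality {X.shape[1]}"
        )
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    layer = _init_layer(X.shape[1], hidden_size, rng)
    if hyper.max_pretrain_epochs == 0:
        return layer

    arrays = [layer.encode_weights, layer.encode_bias, layer.decode_weights, layer.decode_bias]
    x0, shapes = _flatten(arrays)

    def fun(vec):
        ew, eb, dw, db = _unflatten(vec, shapes)
        lay = AutoencoderLayer(ew, eb, dw, db)
        cost, g = ae_cost_and_gradient(lay, X, hyper)
        gvec, _ = _flatten([g["encode_weights"], g["encode_bias"], g["decode_weights"], g["decode_bias"]])
        return cost, gvec

    xf, _ = gradient_descent(fun, x0, hyper.max_pretrain_epochs, hyper.learning_rate, hyper.momentum)
    ew, eb, dw, db = _unflatten(xf, shapes)
    return AutoencoderLayer(ew, eb, dw, db)


def train_stack(
    X: np.ndarray,
    hyper: SAEHyperparams,
    rng: np.random.Generator | int | None = None,
    layer_callback=None,
) -> list[AutoencoderLayer]:
    """Greedy layer-wise pretraining.

    Autoencoder k is trained on the data encoded through layers 1..k-1;
    ``layer_callback(k, training_input)`` exposes each layer's actual
    training input for instrumentation.
    """
    sizes = tuple(hyper.layer_sizes)
    if any(b >= a for a, b in zip((X.shape[1],) + sizes, sizes)):
        raise ValueError(f"layer sizes {sizes} must be strictly decreasing below input size {X.shape[1]}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    children = rng.spawn(len(sizes))
    layers: list[AutoencoderLayer] = []
    H = np.asarray(X, dtype=float)
    for k, (size, child) in enumerate(zip(sizes, children)):
        if layer_callback is not None:
            layer_callback(k, H)
        layer = train_autoencoder(H, size, hyper, child)
        layers.append(layer)
        H = encode(layer, H)
    return layers


def train_softmax(
    H: np.ndarray,
    labels: np.ndarray,
    iterations: int = 200,
    rng: np.random.Generator | int | None = None,
    learning_rate: float = 1.0,
    momentum: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Train the softmax head by full-batch cross-entropy descent.

    Initialization is at zero (the cross-entropy is convex in the
    softmax parameters), so the result is deterministic.
    """
    H = np.asarray(H, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("softmax training needs at least 2 classes present")
    n_classes = int(labels.max()) + 1
    W = np.zeros((n_classes, H.shape[1]))
    b = np.zeros(n_classes)
    x0, shapes = _flatten([W, b])

    def fun(vec):
        Wv, bv = _unflatten(vec, shapes)
        cost, gW, gb = softmax_cost_and_gradient(Wv, bv, H, labels)
        gvec, _ = _flatten([gW, gb])
        return cost, gvec

    xf, _ = gradient_descent(fun, x0, iterations, learning_rate, momentum)
    W, b = _unflatten(xf, shapes)
    return W, b


def _forward(network: StackedNetwork, X: np.ndarray) -> list[np.ndarray]:
    """Activations [A0, A1, ..., AL] through the encoder stack (input
    already scaled)."""
    acts = [X]
    for layer in network.layers:
        acts.append(expit(acts[-1] @ layer.encode_weights.T + layer.encode_bias))
    return acts


def network_cost_and_gradient(
    network: StackedNetwork, Xs: np.ndarray, labels: np.ndarray
) -> tuple[float, list[np.ndarray]]:
    """Cross-entropy of the full network and gradients for every
    parameter, ordered [W1, b1, ..., WL, bL, Wsoft, bsoft].  ``Xs`` must
    already be scaler-transformed."""
    n = Xs.shape[0]
    acts = _forward(network, Xs)
    P = softmax_probabilities(acts[-1], network.softmax_weights, network.softmax_bias)
    eps = np.finfo(float).tiny
    cost = -np.mean(np.log(P[np.arange(n), labels] + eps))
    Y = np.zeros_like(P)
    Y[np.arange(n), labels] = 1.0
    dZ = (P - Y) / n
    g_soft_w = dZ.T @ acts[-1]
    g_soft_b = dZ.sum(axis=0)
    dA = dZ @ network.softmax_weights
    grads: list[np.ndarray] = []
    for l in range(len(network.layers) - 1, -1, -1):
        A = acts[l + 1]
        dZl = dA * A * (1 - A)
        grads.append(dZl.sum(axis=0))  # bias
        grads.append(dZl.T @ acts[l])  # weights
        dA = dZl @ network.layers[l].encode_weights
    grads.reverse()
    grads.extend([g_soft_w, g_soft_b])
    return float(cost), grads


def _network_params(network: StackedNetwork) -> list[np.ndarray]:
    arrays = []
    for layer in network.layers:
        arrays.extend([layer.encode_weights, layer.encode_bias])
    arrays.extend([network.softmax_weights, network.softmax_bias])
    return arrays


def _set_network_params(network: StackedNetwork, arrays: list[np.ndarray]) -> None:
    i = 0
    for layer in network.layers:
        layer.encode_weights, layer.encode_bias = arrays[i], arrays[i + 1]
        i += 2
    network.softmax_weights, network.softmax_bias = arrays[i], arrays[i + 1]


def fine_tune(
    network: StackedNetwork,
    X: np.ndarray,
    labels: np.ndarray,
    hyper: SAEHyperparams,
    X_val: np.ndarray | None = None,
    labels_val: np.ndarray | None = None,
    iterations: int | None = None,
) -> StackedNetwork:
    """Joint cross-entropy backpropagation through all layers.

    With a validation set, the parameters with the lowest validation
    cross-entropy seen during descent are returned (early stopping);
    otherwise the final iterate is returned.  The training loss after
    fine-tuning never exceeds the loss before.
    """
    labels = np.asarray(labels, dtype=int)
    if X.shape[1] != network.input_size:
        raise ValueError(f"features have {X.shape[1]} columns, network expects {network.input_size}")
    net = network.copy()
    n_iter = hyper.finetune_iterations if iterations is None else iterations
    if n_iter == 0:
        return net
    Xs = net.scaler.transform(X) if net.scaler is not None else np.asarray(X, dtype=float)
    if X_val is not None:
        Xv = net.scaler.transform(X_val) if net.scaler is not None else np.asarray(X_val, dtype=float)
        yv = np.asarray(labels_val, dtype=int)

    x0, shapes = _flatten(_network_params(net))

    def fun(vec):
        _set_network_params(net, _unflatten(vec, shapes))
        cost, grads = network_cost_and_gradient(net, Xs, labels)
        gvec, _ = _flatten(grads)
        return cost, gvec

    best = {"vec": x0.copy(), "val": np.inf}

    def callback(it, vec, f):
        if X_val is None:
            return
        _set_network_params(net, _unflatten(vec, shapes))
        val_cost, _ = network_cost_and_gradient(net, Xv, yv)
        if val_cost < best["val"]:
            best["val"] = val_cost
            best["vec"] = vec.copy()

    xf, _ = gradient_descent(fun, x0, n_iter, hyper.learning_rate, hyper.momentum, callback)
    if X_val is not None and np.isfinite(best["val"]):
        xf = best["vec"]
    _set_network_params(net, _unflatten(xf, shapes))
    return net


def initialize_network(
    n_features: int,
    layer_sizes: tuple[int, ...],
    n_classes: int = 2,
    rng: np.random.Generator | int | None = None,
    scaler: FeatureScaler | None = None,
) -> StackedNetwork:
    """Randomly initialized network of the given architecture (used both
    as the MLP starting point and in tests)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sizes = (n_features,) + tuple(layer_sizes)
    layers = [_init_layer(sizes[i], sizes[i + 1], rng) for i in range(len(sizes) - 1)]
    return StackedNetwork(
        layers=layers,
        softmax_weights=_init_matrix((n_classes, sizes[-1]), rng),
        softmax_bias=np.zeros(n_classes),
        scaler=scaler,
    )


def train_sae(
    X: np.ndarray,
    labels: np.ndarray,
    hyper: SAEHyperparams | None = None,
    rng: np.random.Generator | int | None = None,
    X_val: np.ndarray | None = None,
    labels_val: np.ndarray | None = None,
) -> StackedNetwork:
    """Full stacked-autoencoder training: scale, greedily pretrain,
    train the softmax head, assemble, and fine-tune end to end."""
    hyper = hyper or SAEHyperparams()
    if rng is None:
        rng = hyper.seed
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)

    scaler = FeatureScaler.fit(X)
    Xs = scaler.transform(X)
    layers = train_stack(Xs, hyper, rng)
    H = Xs
    for layer in layers:
        H = encode(layer, H)
    W, b = train_softmax(H, labels, hyper.softmax_iterations, rng)
    net = StackedNetwork(layers=layers, softmax_weights=W, softmax_bias=b, scaler=scaler)
    net.meta["model"] = "sae"
    return fine_tune(net, X, labels, hyper, X_val=X_val, labels_val=labels_val)


def predict(network: StackedNetwork, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels (argmax; ties break to the lower class index) and
    class probabilities for each row."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != network.input_size:
        raise ValueError(f"input has shape {X.shape}, network expects {network.input_size} columns")
    Xs = network.scaler.transform(X) if network.scaler is not None else X
    acts = _forward(network, Xs)
    P = softmax_probabilities(acts[-1], network.softmax_weights, network.softmax_bias)
    return np.argmax(P, axis=1), P


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Serialize a StackedNetwork or LdaModel to the HDF5 container."""
    import h5py

    from p300sae.baselines import LdaModel

    with h5py.File(path, "w") as f:
        if isinstance(model, StackedNetwork):
            f.attrs["model_type"] = "stacked"
            f.attrs["architecture"] = model.architecture
            for i, layer in enumerate(model.layers):
                g = f.create_group(f"layer{i}")
                g.create_dataset("encode_weights", data=layer.encode_weights)
                g.create_dataset("encode_bias", data=layer.encode_bias)
                g.create_dataset("decode_weights", data=layer.decode_weights)
                g.create_dataset("decode_bias", data=layer.decode_bias)
            f.create_dataset("softmax_weights", data=model.softmax_weights)
            f.create_dataset("softmax_bias", data=model.softmax_bias)
            if model.scaler is not None:
                g = f.create_group("scaler")
                g.create_dataset("col_min", data=model.scaler.col_min)
                g.create_dataset("col_max", data=model.scaler.col_max)
                g.attrs["lo"], g.attrs["hi"] = model.scaler.lo, model.scaler.hi
        elif isinstance(model, LdaModel):
            f.attrs["model_type"] = "lda"
            f.create_dataset("weight_vector", data=model.weight_vector)
            f.attrs["threshold"] = model.threshold
            f.attrs["shrinkage_intensity"] = model.shrinkage_intensity
            f.create_dataset("class_means", data=model.class_means)
        else:
            raise TypeError(f"cannot serialize model of type {type(model)}")


def load_model(path):
    import h5py

    from p300sae.baselines import LdaModel

    with h5py.File(path, "r") as f:
        kind = f.attrs["model_type"]
        if kind == "stacked":
            layers = []
            i = 0
            while f"layer{i}" in f:
                g = f[f"layer{i}"]
                layers.append(
                    AutoencoderLayer(
                        g["encode_weights"][()],
                        g["encode_bias"][()],
                        g["decode_weights"][()],
                        g["decode_bias"][()],
                    )
                )
                i += 1
            scaler = None
            if "scaler" in f:
                g = f["scaler"]
                scaler = FeatureScaler(
                    g["col_min"][()], g["col_max"][()], float(g.attrs["lo"]), float(g.attrs["hi"])
                )
            return StackedNetwork(
                layers=layers,
                softmax_weights=f["softmax_weights"][()],
                softmax_bias=f["softmax_bias"][()],
                scaler=scaler,
            )
        if kind == "lda":
            return LdaModel(
                weight_vector=f["weight_vector"][()],
                threshold=float(f.attrs["threshold"]),
                shrinkage_intensity=float(f.attrs["shrinkage_intensity"]),
                class_means=f["class_means"][()],
            )
        raise ValueError(f"unknown model type {kind!r} in {path}")
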