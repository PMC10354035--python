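"""Feed-forward networks trained by back-propagation on dosage blocks.

The networks here exist to be *read*, not deployed: after fitting, the
first-hidden-layer weight matrix is handed to the importance methods in
:mod:`snptrace.feature_select`. Training is deliberately plain — logistic
activations throughout, squared-error loss, full-batch gradient descent
with a fixed learning rate — so that the fitted weights are a transparent
function of the data and seed.

Two label encodings are supported. ``one_hot`` gives one logistic output
unit per breed (default for two-hidden-layer networks). ``scaled_class_index``
maps the class index onto [0, 1] and uses a single output unit, the form
required by the classic Garson/Olden importance algorithms, which are
defined for single-hidden-layer, single-output networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "NetworkWeights",
    "TrainingConfig",
    "TrainingDivergenceError",
    "partition_snps",
    "mean_impute",
    "encode_labels",
    "train_network",
    "predict",
    "predict_classes",
    "loss_and_gradients",
]


class TrainingDivergenceError(RuntimeError):
    """Loss became non-finite during training (learning rate too large)."""


@dataclass
class NetworkWeights:
    """Weights and biases of a fitted feed-forward network.

    ``weights[l]`` has shape ``(layer_sizes[l], layer_sizes[l+1])`` (rows =
    source units); ``biases[l]`` has shape ``(layer_sizes[l+1],)``.
    ``classes`` records the label ordering used at training time so
    predictions can be decoded.
    """

    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    output_mode: str = "one_hot"
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        self.biases = [np.asarray(b, dtype=float) for b in self.biases]
        n_trans = len(self.layer_sizes) - 1
        if len(self.weights) != n_trans or len(self.biases) != n_trans:
            raise ValueError("weights/biases do not match layer_sizes transitions")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            expect = (self.layer_sizes[l], self.layer_sizes[l + 1])
            if w.shape != expect:
                raise ValueError(f"weight matrix {l} has shape {w.shape}, expected {expect}")
            if b.shape != (self.layer_sizes[l + 1],):
                raise ValueError(f"bias vector {l} has wrong length")
            if not (np.isfinite(w).all() and np.isfinite(b).all()):
                raise ValueError(f"non-finite parameters in layer {l}")

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_hidden_layers(self) -> int:
        return len(self.layer_sizes) - 2

    @property
    def first_layer(self) -> np.ndarray:
        """Input-to-first-hidden weight matrix (n_inputs x n_hidden1)."""
        return self.weights[0]

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "layer_sizes": self.layer_sizes,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "output_mode": self.output_mode,
            "classes": self.classes,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkWeights":
        d = json.loads(Path(path).read_text())
        return cls(
            layer_sizes=d["layer_sizes"],
            weights=[np.array(w) for w in d["weights"]],
            biases=[np.array(b) for b in d["biases"]],
            output_mode=d.get("output_mode", "one_hot"),
            classes=d.get("classes", []),
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters for back-propagation training.

    ``hidden_layers`` of (40, 38) gives the two-hidden-layer network used
    for first-layer weight selection; (40,) the single-hidden-layer network
    for Garson/Olden. Convergence is declared when the absolute epoch-to-
    epoch loss change stays below ``convergence_tol`` for 5 consecutive
    epochs.
    """

    hidden_layers: tuple[int, ...] = (40, 38)
    activation: str = "logistic"
    output_mode: str = "one_hot"  # or "scaled_class_index"
    learning_rate: float = 1.0
    max_epochs: int = 600
    convergence_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_layers or any(h < 1 for h in self.hidden_layers):
            raise ValueError("hidden layer node counts must be >= 1")
        if self.activation != "logistic":
            raise ValueError("only logistic activation is supported")
        if self.output_mode not in ("one_hot", "scaled_class_index"):
            raise ValueError(f"unknown output_mode {self.output_mode!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


# ---------------------------------------------------------------------------
# data plumbing


def partition_snps(G: GenotypeMatrix, chunk_size: int) -> list[GenotypeMatrix]:
    """Split ``G`` into consecutive non-overlapping column blocks.

    All blocks have ``chunk_size`` SNPs except possibly the last;
    concatenating the blocks reproduces ``G``'s column order.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    return [
        G.take_snps(range(start, min(start + chunk_size, G.n_snps)))
        for start in range(0, G.n_snps, chunk_size)
    ]


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-SNP mean of called genotypes.

    An all-missing column is imputed to 1 (the mid-dosage), which carries
    no information and cannot influence training.
    """
    X = np.asarray(dosages, dtype=float)
    miss = dosages == MISSING
    if not miss.any():
        return X
    X = X.copy()
    X[miss] = np.nan
    col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
    col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)
    idx = np.where(miss)
    X[idx] = col_mean[idx[1]]
    return X


def encode_labels(labels: Sequence[str], output_mode: str) -> tuple[np.ndarray, list[str]]:
    """Encode breed labels as network targets.

    one_hot: one column per class (sorted), 0/1 targets.
    scaled_class_index: single column, class index mapped onto [0, 1].
    """
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 distinct labels")
    index = {c: k for k, c in enumerate(classes)}
    idx = np.array([index[l] for l in labels])
    if output_mode == "one_hot":
        Y = np.zeros((len(labels), len(classes)))
        Y[np.arange(len(labels)), idx] = 1.0
    elif output_mode == "scaled_class_index":
        Y = (idx / (len(classes) - 1)).reshape(-1, 1)
    else:
        raise ValueError(f"unknown output_mode {output_mode!r}")
    return Y, classes


# ---------------------------------------------------------------------------
# forward / backward


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(net: NetworkWeights, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer, input included; logistic at every layer."""
    acts = [X]
    a = X
    for w, b in zip(net.weights, net.biases):
        a = _sigmoid(a @ w + b)
        acts.append(a)
    return acts


def loss_and_gradients(
    net: NetworkWeights, X: np.ndarray, Y: np.ndarray
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Mean squared-error loss and its analytic gradients.

    Loss = (1 / 2n) * sum over samples and outputs of (a - y)^2. Exposed
    separately from training so the back-propagation can be checked against
    finite differences.
    """
    n = X.shape[0]
    acts = _forward(net, X)
    out = acts[-1]
    loss = 0.5 * np.sum((out - Y) ** 2) / n
    delta = (out - Y) * out * (1.0 - out) / n
    grads_w: list[np.ndarray] = [None] * len(net.weights)  # type: ignore[list-item]
    grads_b: list[np.ndarray] = [None] * len(net.biases)  # type: ignore[list-item]
    for l in range(len(net.weights) - 1, -1, -1):
        grads_w[l] = acts[l].T @ delta
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            a = acts[l]
            delta = (delta @ net.weights[l].T) * a * (1.0 - a)
    return float(loss), grads_w, grads_b


def _init_network(n_inputs: int, n_outputs: int, cfg: TrainingConfig, classes: list[str]) -> NetworkWeights:
    sizes = [n_inputs, *cfg.hidden_layers, n_outputs]
    rng = np.random.default_rng(cfg.seed)
    weights, biases = [], []
    for l in range(len(sizes) - 1):
        # fan-in scaled so raw 0/1/2 inputs do not saturate wide layers
        a = 1.0 / np.sqrt(sizes[l])
        weights.append(rng.uniform(-a, a, size=(sizes[l], sizes[l + 1])))
        biases.append(np.zeros(sizes[l + 1]))
    return NetworkWeights(sizes, weights, biases, cfg.output_mode, classes)


def train_network(
    X: np.ndarray | GenotypeMatrix,
    labels: Sequence[str] | None = None,
    cfg: TrainingConfig = TrainingConfig(),
) -> tuple[NetworkWeights, float]:
    """Fit a network to a dosage block by full-batch gradient descent.

    ``X`` may be a :class:`GenotypeMatrix` (labels taken from its breeds,
    missing dosages mean-imputed) or a complete numeric array with
    ``labels`` given. Inputs are fed raw (0/1/2, unscaled). Deterministic
    given ``cfg.seed``. Returns the fitted weights and the final loss.
    """
    if isinstance(X, GenotypeMatrix):
        labels = list(X.breeds)
        Xmat = mean_impute(X.dosages)
    else:
        Xmat = np.asarray(X, dtype=float)
        if labels is None:
            raise ValueError("labels are required for array input")
        if np.any(Xmat == MISSING) or not np.isfinite(Xmat).all():
            raise ValueError("array input must be complete; impute missing dosages first")
    Y, classes = encode_labels(labels, cfg.output_mode)
    net = _init_network(Xmat.shape[1], Y.shape[1], cfg, classes)

    # the returned network is the best iterate seen, so the reported loss
    # can never exceed the loss at initialization
    best_loss = np.inf
    best: tuple[list[np.ndarray], list[np.ndarray]] | None = None
    loss_prev = np.inf
    calm = 0
    for _epoch in range(cfg.max_epochs):
        loss, gw, gb = loss_and_gradients(net, Xmat, Y)
        if not np.isfinite(loss):
            raise TrainingDivergenceError(
                "training loss became non-finite; reduce the learning rate"
            )
        if loss < best_loss:
            best_loss = loss
            best = ([w.copy() for w in net.weights], [b.copy() for b in net.biases])
        if abs(loss_prev - loss) < cfg.convergence_tol:
            calm += 1
            if calm >= 5:
                break
        else:
            calm = 0
        loss_prev = loss
        for l in range(len(net.weights)):
            net.weights[l] -= cfg.learning_rate * gw[l]
            net.biases[l] -= cfg.learning_rate * gb[l]
    final_loss, _, _ = loss_and_gradients(net, Xmat, Y)
    if final_loss < best_loss:
        best_loss = final_loss
    elif best is not None:
        net.weights, net.biases = best
    return net, float(best_loss)


def predict(net: NetworkWeights, X: np.ndarray) -> np.ndarray:
    """Forward pass; returns per-sample output activations."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != net.n_inputs:
        raise ValueError(
            f"input has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"network expects {net.n_inputs}"
        )
    return _forward(net, X)[-1]


def predict_classes(net: NetworkWeights, X: np.ndarray) -> list[str]:
    """Decode predictions back to training labels."""
    if not net.classes:
        raise ValueError("network carries no class labels")
    out = predict(net, X)
    if net.output_mode == "one_hot":
        idx = out.argmax(axis=1)
    else:  # nearest scaled class index
        k = len(net.classes)
        idx = np.clip(np.rint(out[:, 0] * (k - 1)), 0, k - 1).astype(int)
    return [net.classes[i] for i in idx]
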