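"""Multi-layer perceptron baseline: 3 sigmoid hidden layers of 5 nodes and
a single sigmoid output, trained either by full-batch backpropagation with
momentum or by a population metaheuristic acting on the flattened weight
vector.

Targets for the MLP are {0, 1} (sigmoid output, decision threshold 0.5);
the +/-1 convention used by the ELM family is remapped internally, and
predictions are mapped back to +/-1.  The training loss is the least-mean-
square error E(w) = 1/2 * sum_s (output_s - target_s)^2 over the batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import FeatureTable
from .optimizers import OptimizerConfig, optimize, ConvergenceTrace

__all__ = [
    "MlpNetwork",
    "BpConfig",
    "MomentumState",
    "mlp_forward",
    "lms_error",
    "bp_step",
    "train_bp",
    "train_metaheuristic_mlp",
    "mlp_param_count",
    "encode_mlp",
    "decode_mlp",
    "mlp_predict",
]

HIDDEN_LAYOUT = (5, 5, 5)  # three hidden layers, five nodes each


@dataclass
class MlpNetwork:
    """Fully connected sigmoid network with layer sizes [d, 5, 5, 5, 1]."""

    weights: list[np.ndarray]  # per layer, (in, out)
    biases: list[np.ndarray]  # per layer, (out,)

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("one bias vector per weight matrix required")
        for li, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.ndim != 2 or b.shape != (W.shape[1],):
                raise ValueError(f"layer {li}: incompatible weight/bias shapes")
            if li > 0 and W.shape[0] != self.weights[li - 1].shape[1]:
                raise ValueError(f"layer {li}: input size mismatch")
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise ValueError(f"layer {li}: non-finite parameters")

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [W.shape[1] for W in self.weights]

    def copy(self) -> "MlpNetwork":
        return MlpNetwork([W.copy() for W in self.weights], [b.copy() for b in self.biases])

    def to_dict(self) -> dict:
        return {
            "kind": "mlp",
            "layer_sizes": self.layer_sizes,
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "activation": "sigmoid",
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, obj: dict) -> "MlpNetwork":
        return cls(
            [np.asarray(W, dtype=float) for W in obj["weights"]],
            [np.asarray(b, dtype=float) for b in obj["biases"]],
        )

    @classmethod
    def load(cls, path) -> "MlpNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class BpConfig:
    """Backprop-with-momentum settings: learning rate ``epsilon`` > 0,
    momentum ``alpha`` in [0, 1], full-batch ``epochs``."""

    epsilon: float = 0.01
    alpha: float = 0.9
    epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")


@dataclass
class MomentumState:
    """Previous parameter updates, shape-mirroring the network; zeros at
    the start of training."""

    d_weights: list[np.ndarray]
    d_biases: list[np.ndarray]

    @classmethod
    def zeros_like(cls, net: MlpNetwork) -> "MomentumState":
        return cls(
            [np.zeros_like(W) for W in net.weights],
            [np.zeros_like(b) for b in net.biases],
        )


def init_network(d: int, seed: int | None = None, low: float = -1.0, high: float = 1.0) -> MlpNetwork:
    """Random [low, high] uniform initialization of the [d, 5, 5, 5, 1] net."""
    rng = np.random.default_rng(seed)
    sizes = [d, *HIDDEN_LAYOUT, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.uniform(low, high, size=(fan_in, fan_out)))
        biases.append(rng.uniform(low, high, size=fan_out))
    return MlpNetwork(weights, biases)


def mlp_forward(net: MlpNetwork, X: np.ndarray) -> list[np.ndarray]:
    """Forward pass; returns the list of layer activations, input first.

    The input layer passes features through unchanged; every subsequent
    node applies a sigmoid to its weighted input sum, so the output lies
    strictly in (0, 1).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input")
    activations = [X]
    for W, b in zip(net.weights, net.biases):
        activations.append(expit(activations[-1] @ W + b))
    return activations


def lms_error(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Least-mean-square batch error 1/2 * sum (output - target)^2."""
    outputs = np.asarray(outputs, dtype=float).ravel()
    targets = np.asarray(targets, dtype=float).ravel()
    if outputs.shape != targets.shape:
        raise ValueError("outputs and targets lengths differ")
    return 0.5 * float(np.sum((outputs - targets) ** 2))


def _gradients(net: MlpNetwork, X: np.ndarray, t01: np.ndarray):
    """Full-batch gradient of the LMS error by backpropagation."""
    acts = mlp_forward(net, X)
    out = acts[-1]
    delta = (out - t01.reshape(out.shape)) * out * (1.0 - out)
    gW, gb = [], []
    for li in range(len(net.weights) - 1, -1, -1):
        gW.append(acts[li].T @ delta)
        gb.append(delta.sum(axis=0))
        if li > 0:
            a = acts[li]
            delta = (delta @ net.weights[li].T) * a * (1.0 - a)
    return gW[::-1], gb[::-1]


def bp_step(
    net: MlpNetwork,
    X: np.ndarray,
    targets01: np.ndarray,
    config: BpConfig,
    state: MomentumState,
) -> tuple[MlpNetwork, MomentumState]:
    """One full-batch gradient step with momentum:
    ``dw(t) = -epsilon * dE/dw + alpha * dw(t-1)``.  Returns a new network
    and updated momentum state."""
    if len(np.atleast_2d(X)) == 0:
        raise ValueError("empty batch")
    gW, gb = _gradients(net, X, np.asarray(targets01, dtype=float))
    new_net = net.copy()
    dW = [
        -config.epsilon * g + config.alpha * prev
        for g, prev in zip(gW, state.d_weights)
    ]
    db = [
        -config.epsilon * g + config.alpha * prev
        for g, prev in zip(gb, state.d_biases)
    ]
    for li in range(len(new_net.weights)):
        if not (np.all(np.isfinite(dW[li])) and np.all(np.isfinite(db[li]))):
            raise ValueError("non-finite gradient")
        new_net.weights[li] += dW[li]
        new_net.biases[li] += db[li]
    return new_net, MomentumState(dW, db)


def train_bp(train: FeatureTable, config: BpConfig) -> MlpNetwork:
    """Train the MLP by ``epochs`` full-batch backprop steps; the seed
    fixes the initial weights, so training is deterministic."""
    net = init_network(train.d, seed=config.seed)
    t01 = (train.labels == 1).astype(float)
    state = MomentumState.zeros_like(net)
    for _ in range(config.epochs):
        net, state = bp_step(net, train.features, t01, config, state)
    return net


def mlp_param_count(d: int) -> int:
    sizes = [d, *HIDDEN_LAYOUT, 1]
    return sum((i + 1) * o for i, o in zip(sizes[:-1], sizes[1:]))


def encode_mlp(net: MlpNetwork) -> np.ndarray:
    """Flatten all parameters layer by layer (weights column-major, then
    the bias vector) into one design vector."""
    parts = []
    for W, b in zip(net.weights, net.biases):
        parts.append(W.ravel(order="F"))
        parts.append(b)
    return np.concatenate(parts)


def decode_mlp(z: np.ndarray, d: int) -> MlpNetwork:
    """Inverse of :func:`encode_mlp` for the [d, 5, 5, 5, 1] layout."""
    z = np.asarray(z, dtype=float)
    if z.shape != (mlp_param_count(d),):
        raise ValueError(f"expected vector of length {mlp_param_count(d)}")
    sizes = [d, *HIDDEN_LAYOUT, 1]
    weights, biases, pos = [], [], 0
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        k = fan_in * fan_out
        weights.append(z[pos : pos + k].reshape((fan_in, fan_out), order="F"))
        pos += k
        biases.append(z[pos : pos + fan_out].copy())
        pos += fan_out
    return MlpNetwork(weights, biases)


def mlp_predict(net: MlpNetwork, X: np.ndarray) -> np.ndarray:
    """+/-1 labels from the sigmoid output at threshold 0.5 (tie -> +1)."""
    out = mlp_forward(net, X)[-1].ravel()
    return np.where(out >= 0.5, 1, -1)


def train_metaheuristic_mlp(
    variant: str,
    train: FeatureTable,
    config: OptimizerConfig | None = None,
    **overrides,
) -> tuple[MlpNetwork, ConvergenceTrace]:
    """Optimize the flattened MLP parameters with Jaya/CJaya/TLBO, using
    the training misclassification rate as the objective."""
    D = mlp_param_count(train.d)
    if config is None:
        config = OptimizerConfig(variant=variant, dims=D, **overrides)
    else:
        from dataclasses import replace

        config = replace(config, variant=variant, dims=D)
    X, y = train.features, train.labels

    def objective(z: np.ndarray) -> float:
        pred = mlp_predict(decode_mlp(z, train.d), X)
        return float(np.mean(pred != y))

    best, trace = optimize(objective, config)
    return decode_mlp(best.z, train.d), trace
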