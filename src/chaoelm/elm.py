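"""Extreme learning machine (ELM) core.

An ELM is a single-hidden-layer feed-forward network whose hidden weights
and biases are drawn at random and never tuned; only the output weights
``beta`` are learned, in closed form, as the minimum-norm least-squares
solution ``beta = pinv(H) @ T`` where ``H`` is the hidden-layer activation
matrix and ``T`` the +/-1 target vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import FeatureTable, NormalizationSpec

__all__ = [
    "ElmModel",
    "random_hidden_layer",
    "hidden_activations",
    "solve_output_weights",
    "predict_scores",
    "classify",
    "train_elm",
]


@dataclass
class ElmModel:
    """A (possibly trained) ELM.

    ``weights`` is the d x H input-to-hidden matrix, ``bias`` the length-H
    hidden bias vector and ``beta`` the length-H output weights (``None``
    before training).  ``normalization`` optionally carries the feature
    scaling fitted with the model so raw inputs can be scored directly.
    """

    weights: np.ndarray
    bias: np.ndarray
    beta: np.ndarray | None = None
    activation: str = "sigmoid"
    seed: int | None = None
    normalization: NormalizationSpec | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weights.ndim != 2 or self.bias.shape != (self.weights.shape[1],):
            raise ValueError("weights must be d x H with bias of length H")
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.bias))):
            raise ValueError("non-finite model parameters")
        if self.activation != "sigmoid":
            raise ValueError(f"unsupported activation {self.activation!r}")

    @property
    def d(self) -> int:
        return self.weights.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.weights.shape[1]

    @property
    def is_trained(self) -> bool:
        return self.beta is not None

    def to_dict(self) -> dict:
        obj = {
            "kind": "elm",
            "weights": self.weights.tolist(),
            "bias": self.bias.tolist(),
            "beta": None if self.beta is None else self.beta.tolist(),
            "activation": self.activation,
            "hidden_size": self.hidden_size,
            "seed": self.seed,
        }
        if self.normalization is not None:
            obj["normalization"] = self.normalization.to_dict()
        return obj

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, obj: dict) -> "ElmModel":
        norm = obj.get("normalization")
        return cls(
            weights=np.asarray(obj["weights"], dtype=float),
            bias=np.asarray(obj["bias"], dtype=float),
            beta=None if obj["beta"] is None else np.asarray(obj["beta"], dtype=float),
            activation=obj.get("activation", "sigmoid"),
            seed=obj.get("seed"),
            normalization=None if norm is None else NormalizationSpec.from_dict(norm),
        )

    @classmethod
    def load(cls, path) -> "ElmModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def random_hidden_layer(
    d: int,
    hidden: int,
    seed: int | None = None,
    low: float = -1.0,
    high: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw i.i.d. uniform input weights (d x H) and biases (H,) on
    ``[low, high]``; reproducible from ``seed``."""
    if hidden < 1:
        raise ValueError("hidden-neuron count must be >= 1")
    if low >= high:
        raise ValueError("require low < high")
    if rng is None:
        rng = np.random.default_rng(seed)
    W = rng.uniform(low, high, size=(d, hidden))
    b = rng.uniform(low, high, size=hidden)
    return W, b


def hidden_activations(X: np.ndarray, W: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Sigmoid hidden-layer output matrix: entry (s, i) is
    ``sigmoid(x_s . w_i + b_i)``, strictly inside (0, 1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input")
    if X.shape[1] != W.shape[0]:
        raise ValueError(f"input has {X.shape[1]} features, weights expect {W.shape[0]}")
    return expit(X @ W + bias)


def solve_output_weights(
    Hm: np.ndarray, T: np.ndarray, ridge: float = 0.0
) -> np.ndarray:
    """Minimum-norm least-squares output weights ``beta = pinv(Hm) @ T``.

    Uses an SVD-based solve with singular values below
    ``eps * max(n, H) * sigma_max`` treated as zero.  ``ridge > 0`` switches
    to the Tikhonov-regularized normal equations for ill-conditioned
    activation matrices.
    """
    Hm = np.asarray(Hm, dtype=float)
    T = np.asarray(T, dtype=float)
    if Hm.ndim != 2 or T.shape != (Hm.shape[0],):
        raise ValueError("activation matrix rows must match target length")
    if ridge > 0:
        H = Hm.shape[1]
        return np.linalg.solve(Hm.T @ Hm + ridge * np.eye(H), Hm.T @ T)
    beta, *_ = np.linalg.lstsq(Hm, T, rcond=None)
    return beta


def predict_scores(model: ElmModel, X: np.ndarray) -> np.ndarray:
    """Real-valued network output ``hidden_activations(X) @ beta``."""
    if not model.is_trained:
        raise ValueError("model has no output weights; train it first")
    return hidden_activations(X, model.weights, model.bias) @ model.beta


def classify(scores: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Threshold scores into +/-1 labels; a score exactly at the threshold
    is assigned to the positive class."""
    return np.where(np.asarray(scores) >= threshold, 1, -1)


def train_elm(
    train: FeatureTable,
    hidden: int,
    seed: int | None = None,
    low: float = -1.0,
    high: float = 1.0,
    ridge: float = 0.0,
) -> ElmModel:
    """Train a plain ELM: random hidden layer, closed-form ``beta``."""
    W, b = random_hidden_layer(train.d, hidden, seed=seed, low=low, high=high)
    Hm = hidden_activations(train.features, W, b)
    beta = solve_output_weights(Hm, train.labels.astype(float), ridge=ridge)
    return ElmModel(W, b, beta=beta, seed=seed)
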