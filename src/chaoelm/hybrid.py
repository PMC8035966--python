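"""Metaheuristic-optimized ELM (CJaya-ELM and variants).

Plain ELM leaves its hidden layer random.  Here a population optimizer
(Jaya, CJaya or TLBO) searches over that hidden layer instead: each
candidate is a flat vector of length ``(d + 1) * H`` encoding the d x H
input weights plus the H biases, all inside the box [-1, 1]^D.  Evaluating
a candidate decodes it, solves the output weights ``beta`` in closed form
on the training split, and scores the resulting network's
misclassification rate on an evaluation set; the optimizer's greedy loop
minimizes that rate.  The winning candidate is decoded into the returned
:class:`~chaoelm.elm.ElmModel` together with its ``beta``.

Two objective modes are provided:

* ``"paper"`` scores candidates directly on the held-out *test* split.
  This mirrors the original experimental protocol but leaks the test set
  into model selection, so the resulting test metrics are optimistically
  biased.
* ``"validation"`` (leak-free) carves an internal 80/20 validation split
  out of the training data and scores candidates on that; the test split
  is touched only by the final evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import FeatureTable, SplitPair, shuffle_split
from .elm import ElmModel, hidden_activations, predict_scores, solve_output_weights, train_elm
from .metrics import MetricsReport, evaluate_scores
from .optimizers import ConvergenceTrace, OptimizerConfig, optimize

__all__ = [
    "HybridConfig",
    "ObjectiveRecord",
    "encode_layer",
    "decode_layer",
    "candidate_objective",
    "train_hybrid_elm",
    "final_evaluate",
]

OBJECTIVE_MODES = ("paper", "validation")
VALIDATION_FRACTION = 0.8  # internal train share in validation mode


@dataclass
class HybridConfig:
    """Settings for metaheuristic-optimized ELM training.

    ``variant="none"`` falls back to plain ELM (random hidden layer, no
    optimization).  ``objective_mode`` selects the candidate evaluation
    set; see the module docstring.
    """

    variant: str = "cjaya"
    hidden: int = 100
    population: int = 100
    iterations: int = 100
    seed: int = 0
    objective_mode: str = "paper"
    bounds: tuple = (-1.0, 1.0)
    as_printed: bool = False

    def __post_init__(self) -> None:
        if self.variant not in ("none", "jaya", "cjaya", "tlbo"):
            raise ValueError("variant must be none, jaya, cjaya or tlbo")
        if self.hidden < 1:
            raise ValueError("hidden-neuron count must be >= 1")
        if self.variant != "none" and self.population < 2:
            raise ValueError("population size must be >= 2")
        if self.objective_mode not in OBJECTIVE_MODES:
            raise ValueError(f"objective_mode must be one of {OBJECTIVE_MODES}")


@dataclass
class ObjectiveRecord:
    """Misclassification rate of one candidate, with its solved beta."""

    miss_rate: float
    beta: np.ndarray
    index: int | None = None


def encode_layer(W: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Flatten a hidden layer into one candidate vector: the d x H weight
    matrix column-major, followed by the H biases."""
    W = np.asarray(W, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if W.ndim != 2 or bias.shape != (W.shape[1],):
        raise ValueError("W must be d x H with bias of length H")
    return np.concatenate([W.ravel(order="F"), bias])


def decode_layer(z: np.ndarray, d: int, hidden: int) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`encode_layer`."""
    z = np.asarray(z, dtype=float)
    if z.shape != ((d + 1) * hidden,):
        raise ValueError(f"expected vector of length {(d + 1) * hidden}")
    W = z[: d * hidden].reshape((d, hidden), order="F")
    bias = z[d * hidden :].copy()
    return W, bias


def candidate_objective(
    z: np.ndarray,
    train: FeatureTable,
    eval_set: FeatureTable,
    hidden: int,
    ridge: float = 0.0,
) -> ObjectiveRecord:
    """Decode a candidate hidden layer, solve beta on ``train`` and return
    its misclassification rate on ``eval_set``."""
    W, bias = decode_layer(z, train.d, hidden)
    Hm = hidden_activations(train.features, W, bias)
    beta = solve_output_weights(Hm, train.labels.astype(float), ridge=ridge)
    scores = hidden_activations(eval_set.features, W, bias) @ beta
    pred = np.where(scores >= 0.0, 1, -1)
    return ObjectiveRecord(miss_rate=float(np.mean(pred != eval_set.labels)), beta=beta)


def train_hybrid_elm(
    data: SplitPair, config: HybridConfig, ridge: float = 0.0
) -> tuple[ElmModel, ConvergenceTrace]:
    """Train an ELM whose hidden layer is chosen by the configured
    metaheuristic (or at random for ``variant="none"``).

    Returns the trained model and the optimizer's best-miss-rate trace
    (length ``iterations + 1``; a single point for ``variant="none"``).
    """
    if config.variant == "none":
        model = train_elm(data.train, config.hidden, seed=config.seed, ridge=ridge)
        rec = _score_table(model, data.test if config.objective_mode == "paper" else data.train)
        trace = ConvergenceTrace()
        trace.append(rec)
        return model, trace

    if config.objective_mode == "paper":
        fit_table, eval_table = data.train, data.test
    else:
        inner = shuffle_split(
            data.train, ratio=VALIDATION_FRACTION, seed=_child_seed(config.seed)
        )
        fit_table, eval_table = inner.train, inner.test

    D = (data.train.d + 1) * config.hidden

    def objective(z: np.ndarray) -> float:
        return candidate_objective(z, fit_table, eval_table, config.hidden, ridge=ridge).miss_rate

    opt_config = OptimizerConfig(
        variant=config.variant,
        dims=D,
        population=config.population,
        iterations=config.iterations,
        seed=config.seed,
        bounds=config.bounds,
        as_printed=config.as_printed,
    )
    best, trace = optimize(objective, opt_config)
    # the beta solve is deterministic, so re-solving for the winning
    # candidate reproduces exactly the beta recorded during its evaluation
    record = candidate_objective(best.z, fit_table, eval_table, config.hidden, ridge=ridge)
    W, bias = decode_layer(best.z, data.train.d, config.hidden)
    model = ElmModel(W, bias, beta=record.beta, seed=config.seed)
    return model, trace


def _child_seed(seed: int) -> int:
    return int(np.random.SeedSequence([int(seed), 1]).generate_state(1)[0] % (2**31))


def _score_table(model: ElmModel, table: FeatureTable) -> float:
    scores = predict_scores(model, table.features)
    pred = np.where(scores >= 0.0, 1, -1)
    return float(np.mean(pred != table.labels))


def final_evaluate(model: ElmModel, split: SplitPair) -> tuple[MetricsReport, MetricsReport]:
    """Full metric battery of a trained model on the train and test splits."""
    reports = []
    for table in (split.train, split.test):
        scores = predict_scores(model, table.features)
        reports.append(evaluate_scores(scores, table.labels))
    return reports[0], reports[1]
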