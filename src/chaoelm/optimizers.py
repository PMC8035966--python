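"""Population metaheuristics over bounded real vectors: Jaya, Chaotic-Jaya
(CJaya) and teaching-learning-based optimization (TLBO), plus the logistic
chaotic stream that drives CJaya.

All three optimizers share the same skeleton: a population of ``PS``
candidate vectors initialized uniformly inside a box, an update rule that
proposes a move per candidate, clipping to the box, and greedy replacement
(a proposal is accepted only if it strictly lowers the objective).  The
best-so-far objective is therefore non-increasing: every run carries a
:class:`ConvergenceTrace` asserting that elitism.

Jaya moves each candidate toward the current best and away from the current
worst,

    z' = z + r1 * (z_best - |z|) - r2 * (z_worst - |z|),

with fresh uniform multipliers ``r1, r2`` per dimension, candidate and
iteration.  CJaya replaces the uniform multipliers with iterates of the
fully chaotic logistic map ``x <- 4 x (1 - x)``.  TLBO alternates a teacher
phase (move toward the best via the population mean) and a learner phase
(pairwise moves toward better peers / away from worse ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Candidate",
    "Population",
    "ChaoticStream",
    "OptimizerConfig",
    "ConvergenceTrace",
    "logistic_next",
    "jaya_update",
    "cjaya_update",
    "tlbo_teacher_step",
    "tlbo_learner_step",
    "greedy_select",
    "optimize",
]

VARIANTS = ("jaya", "cjaya", "tlbo")

# fixed or eventually-fixed points of the logistic map at r=4; excluded
# from initial states so the stream never collapses
_LOGISTIC_FIXED = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class Candidate:
    """A design vector with its (minimized) objective value."""

    z: np.ndarray
    objective: float | None = None

    @property
    def evaluated(self) -> bool:
        return self.objective is not None


@dataclass
class Population:
    """Candidate matrix (PS x D) with objectives and box bounds."""

    z: np.ndarray
    objectives: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        if self.z.shape[0] < 2:
            raise ValueError("population size must be >= 2")
        if self.objectives.shape != (self.z.shape[0],):
            raise ValueError("one objective per candidate required")

    @property
    def size(self) -> int:
        return self.z.shape[0]

    @property
    def best_index(self) -> int:
        # argmin/argmax resolve ties to the lowest index
        return int(np.argmin(self.objectives))

    @property
    def worst_index(self) -> int:
        return int(np.argmax(self.objectives))

    def best(self) -> Candidate:
        i = self.best_index
        return Candidate(self.z[i].copy(), float(self.objectives[i]))


def logistic_next(x):
    """One step of the logistic map at full chaos: ``4 x (1 - x)``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("logistic map state must lie in [0, 1]")
    out = 4.0 * x * (1.0 - x)
    return float(out) if out.ndim == 0 else out


class ChaoticStream:
    """A bank of independent logistic-map iterates, one per consumer
    dimension.

    Initial states are uniform on (0, 1) excluding the map's fixed and
    eventually-fixed points; each :meth:`draw` advances every dimension by
    one logistic step and returns the new states.  Values never leave
    [0, 1].
    """

    def __init__(self, seed=None, dims: int = 1, rng: np.random.Generator | None = None):
        if dims < 1:
            raise ValueError("dims must be >= 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        state = rng.uniform(0.0, 1.0, size=dims)
        bad = np.isin(state, _LOGISTIC_FIXED)
        while np.any(bad):  # pragma: no cover - measure-zero event
            state[bad] = rng.uniform(0.0, 1.0, size=int(bad.sum()))
            bad = np.isin(state, _LOGISTIC_FIXED)
        self.state = state
        self.t = 0

    @property
    def dims(self) -> int:
        return self.state.shape[0]

    def draw(self) -> np.ndarray:
        self.state = 4.0 * self.state * (1.0 - self.state)
        self.t += 1
        return self.state.copy()


class _UniformStream:
    """Drop-in stream that yields pseudo-random uniforms instead of chaotic
    iterates; used to show CJaya degenerates to Jaya under uniform draws."""

    def __init__(self, rng: np.random.Generator, dims: int):
        self.rng = rng
        self._dims = dims

    @property
    def dims(self) -> int:
        return self._dims

    def draw(self) -> np.ndarray:
        return self.rng.random(self._dims)


@dataclass
class OptimizerConfig:
    """Run settings shared by all variants.

    ``bounds`` is ``(low, high)``, scalars or length-D arrays, defining the
    search box (candidates are clipped to it after every move).
    """

    variant: str = "cjaya"
    dims: int = 1
    population: int = 100
    iterations: int = 100
    seed: int = 0
    bounds: tuple = (-1.0, 1.0)
    as_printed: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.population < 2:
            raise ValueError("population size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.dims < 1:
            raise ValueError("dims must be >= 1")

    def box(self) -> tuple[np.ndarray, np.ndarray]:
        low = np.broadcast_to(np.asarray(self.bounds[0], float), (self.dims,)).copy()
        high = np.broadcast_to(np.asarray(self.bounds[1], float), (self.dims,)).copy()
        if np.any(low >= high):
            raise ValueError("lower bound must be below upper bound")
        return low, high


@dataclass
class ConvergenceTrace:
    """Best-so-far objective after initialization and each iteration."""

    best_objective: list[float] = field(default_factory=list)

    def append(self, value: float) -> None:
        if self.best_objective and value > self.best_objective[-1] + 1e-15:
            raise AssertionError("elitism violated: best objective increased")
        self.best_objective.append(float(value))

    def __len__(self) -> int:
        return len(self.best_objective)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.best_objective)),
                "best_objective": self.best_objective,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def jaya_update(z, z_best, z_worst, r1, r2, as_printed: bool = False):
    """Jaya move toward the best and away from the worst candidate.

    The canonical rule is ``z + r1*(z_best - |z|) - r2*(z_worst - |z|)``;
    ``as_printed=True`` flips the sign of ``|z|`` in the best-attraction
    term (``z_best + |z|``), an alternative form kept for comparison.
    Multipliers ``r1, r2`` must lie in [0, 1], one per dimension.
    """
    z, z_best, z_worst, r1, r2 = map(np.asarray, (z, z_best, z_worst, r1, r2))
    if not (z.shape == z_best.shape == z_worst.shape == r1.shape == r2.shape):
        raise ValueError("all arguments must share one shape")
    az = np.abs(z)
    attract = z_best + az if as_printed else z_best - az
    return z + r1 * attract - r2 * (z_worst - az)


def cjaya_update(z, z_best, z_worst, stream, as_printed: bool = False):
    """Jaya move with the two uniform multipliers replaced by two
    independent per-dimension draws from a chaotic stream."""
    z = np.asarray(z)
    r1 = np.asarray(stream.draw()).reshape(z.shape)
    r2 = np.asarray(stream.draw()).reshape(z.shape)
    return jaya_update(z, z_best, z_worst, r1, r2, as_printed=as_printed)


def greedy_select(old: Candidate, new: Candidate) -> Candidate:
    """Keep the strictly better candidate; ties favour the incumbent."""
    if not (old.evaluated and new.evaluated):
        raise ValueError("both candidates must be evaluated")
    return new if new.objective < old.objective else old


def _evaluate(objective, Z: np.ndarray) -> np.ndarray:
    vals = np.array([float(objective(z)) for z in Z])
    if not np.all(np.isfinite(vals)):
        bad = int(np.flatnonzero(~np.isfinite(vals))[0])
        raise ValueError(
            f"objective returned non-finite value {vals[bad]} at candidate {Z[bad]}"
        )
    return vals


def _try_replace(pop: Population, k: int, proposal: np.ndarray, objective) -> None:
    """Clip a proposal to the box, evaluate it, and greedily replace
    member ``k`` if strictly better (ties keep the incumbent)."""
    proposal = np.clip(proposal, pop.lower, pop.upper)
    value = float(objective(proposal))
    if not np.isfinite(value):
        raise ValueError(
            f"objective returned non-finite value {value} at candidate {proposal}"
        )
    if value < pop.objectives[k]:
        pop.z[k] = proposal
        pop.objectives[k] = value


def tlbo_teacher_step(pop: Population, objective, rng: np.random.Generator) -> None:
    """TLBO teacher phase: every candidate moves toward the best solution
    relative to the population mean, ``z + r * (z_teacher - Tf * mean)``
    with fresh ``r ~ U(0,1)`` per dimension and teaching factor ``Tf``
    drawn from {1, 2} per candidate.

    Candidates are processed sequentially with immediate greedy
    replacement, so an accepted move can become the teacher for the
    candidates after it; the population mean is frozen at phase start.
    """
    mean = pop.z.mean(axis=0)
    for k in range(pop.size):
        teacher = pop.z[pop.best_index]
        tf = int(rng.integers(1, 3))
        r = rng.random(pop.z.shape[1])
        _try_replace(pop, k, pop.z[k] + r * (teacher - tf * mean), objective)


def tlbo_learner_step(pop: Population, objective, rng: np.random.Generator) -> None:
    """TLBO learner phase: each candidate picks a random peer and moves
    toward it if the peer is currently better, away otherwise.  Sequential
    greedy replacement, in place."""
    ps = pop.size
    for k in range(ps):
        j = int(rng.integers(0, ps - 1))
        if j >= k:  # uniform over the *other* members
            j += 1
        r = rng.random(pop.z.shape[1])
        diff = pop.z[j] - pop.z[k]
        if pop.objectives[j] < pop.objectives[k]:
            proposal = pop.z[k] + r * diff
        else:
            proposal = pop.z[k] - r * diff
        _try_replace(pop, k, proposal, objective)


def optimize(objective, config: OptimizerConfig) -> tuple[Candidate, ConvergenceTrace]:
    """Run the configured variant and return the best candidate found plus
    the best-so-far trace (length ``iterations + 1``).

    The objective maps a length-D vector to a finite float to be minimized.
    A single seed drives everything: the initial population, the uniform
    multipliers (Jaya/TLBO) and the chaotic stream's initial states
    (CJaya), so runs are fully reproducible.
    """
    rng = np.random.default_rng(config.seed)
    low, high = config.box()
    Z = rng.uniform(low, high, size=(config.population, config.dims))
    vals = _evaluate(objective, Z)
    pop = Population(Z, vals, low, high)
    trace = ConvergenceTrace()
    trace.append(pop.objectives[pop.best_index])

    stream = None
    if config.variant == "cjaya":
        stream = ChaoticStream(rng=rng, dims=config.dims)

    for _ in range(config.iterations):
        if config.variant == "tlbo":
            tlbo_teacher_step(pop, objective, rng)
            tlbo_learner_step(pop, objective, rng)
        else:
            # sequential with immediate replacement: an accepted move can
            # serve as best/worst for the candidates processed after it
            for k in range(pop.size):
                z_best = pop.z[pop.best_index]
                z_worst = pop.z[pop.worst_index]
                if config.variant == "jaya":
                    r1 = rng.random(config.dims)
                    r2 = rng.random(config.dims)
                    proposal = jaya_update(
                        pop.z[k], z_best, z_worst, r1, r2, as_printed=config.as_printed
                    )
                else:
                    proposal = cjaya_update(
                        pop.z[k], z_best, z_worst, stream, as_printed=config.as_printed
                    )
                _try_replace(pop, k, proposal, objective)
        trace.append(pop.objectives[pop.best_index])

    return pop.best(), trace
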