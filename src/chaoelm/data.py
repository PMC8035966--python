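"""Tabular data handling: feature tables, min-max normalization, shuffled
train/test splits, CSV I/O and a synthetic generator for Pima-style binary
clinical data.

The unit every stage of the pipeline consumes is a :class:`FeatureTable`:
an ``n x d`` numeric feature matrix plus a vector of ``{-1, +1}`` class
labels (+1 = diseased / positive class).  Labels arriving as ``{0, 1}`` in
CSV files are remapped to ``{-1, +1}`` on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureTable",
    "NormalizationSpec",
    "SplitPair",
    "SyntheticSpec",
    "fit_normalization",
    "apply_normalization",
    "invert_normalization",
    "shuffle_split",
    "generate_synthetic",
    "read_csv",
    "write_csv",
]


@dataclass
class FeatureTable:
    """Numeric feature matrix with binary ``{-1, +1}`` labels.

    Parameters
    ----------
    features : ndarray of shape (n, d)
        Clinical measurements, no missing values allowed.
    labels : ndarray of shape (n,)
        Class labels, strictly ``-1`` or ``+1`` (+1 = positive/diseased).
    names : list of str
        Feature names, length ``d``.
    """

    features: np.ndarray
    labels: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, d = self.features.shape
        if n < 1 or d < 1:
            raise ValueError("feature matrix must be non-empty")
        if self.labels.shape != (n,):
            raise ValueError("labels length must match number of rows")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing or non-finite values")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be -1 or +1")
        self.labels = self.labels.astype(int)
        if not self.names:
            self.names = [f"x{j}" for j in range(d)]
        if len(self.names) != d:
            raise ValueError("names length must match number of features")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.features[idx], self.labels[idx], list(self.names))


@dataclass
class NormalizationSpec:
    """Per-feature min-max rescaling onto a target interval ``[a, b]``.

    A raw value ``M`` of feature ``j`` maps to
    ``a + (b - a) * (M - Dmin[j]) / (Dmax[j] - Dmin[j])``.
    """

    a: float
    b: float
    dmin: np.ndarray
    dmax: np.ndarray

    def __post_init__(self) -> None:
        self.dmin = np.asarray(self.dmin, dtype=float)
        self.dmax = np.asarray(self.dmax, dtype=float)
        if not self.a < self.b:
            raise ValueError("require a < b")
        if self.dmin.shape != self.dmax.shape or self.dmin.ndim != 1:
            raise ValueError("dmin/dmax must be 1-D of equal length")
        if np.any(self.dmin > self.dmax):
            raise ValueError("dmin must not exceed dmax")

    @property
    def d(self) -> int:
        return self.dmin.shape[0]

    @property
    def constant_mask(self) -> np.ndarray:
        return self.dmin == self.dmax

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "dmin": self.dmin.tolist(),
            "dmax": self.dmax.tolist(),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "NormalizationSpec":
        return cls(obj["a"], obj["b"], np.asarray(obj["dmin"]), np.asarray(obj["dmax"]))


@dataclass
class SplitPair:
    """Train/test partition produced by :func:`shuffle_split`."""

    train: FeatureTable
    test: FeatureTable
    seed: int
    ratio: float


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic two-class clinical table.

    Feature ``j`` is drawn from a normal distribution truncated to
    non-negative values, centred at ``base_mean[j]`` for the negative class
    and at ``base_mean[j] + effect[j]`` for the positive class, with common
    standard deviation ``noise_sd``.  A ``label_flip`` fraction of labels is
    inverted afterwards to emulate diagnostic label noise.
    """

    n: int = 768
    d: int = 8
    prevalence: float = 0.35
    effect: np.ndarray | float = 0.5
    noise_sd: float = 1.0
    label_flip: float = 0.02
    seed: int = 0
    base_mean: np.ndarray | float = 3.0

    def __post_init__(self) -> None:
        if self.n < 2 or self.d < 1:
            raise ValueError("need n >= 2 and d >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.prevalence * self.n < 1:
            raise ValueError("expected positive count below one sample")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.label_flip < 0.5:
            raise ValueError("label_flip must lie in [0, 0.5)")
        self.effect = np.broadcast_to(
            np.asarray(self.effect, dtype=float), (self.d,)
        ).copy()
        self.base_mean = np.broadcast_to(
            np.asarray(self.base_mean, dtype=float), (self.d,)
        ).copy()
        if np.any(self.base_mean < 0):
            raise ValueError("base_mean must be non-negative")


def fit_normalization(table: FeatureTable, a: float = -1.0, b: float = 1.0) -> NormalizationSpec:
    """Fit per-feature minima/maxima over all rows of ``table``.

    Constant features (``Dmin == Dmax``) are flagged with a warning; the
    transform maps them to the interval midpoint ``(a + b) / 2``.
    """
    if not a < b:
        raise ValueError("require a < b")
    dmin = table.features.min(axis=0)
    dmax = table.features.max(axis=0)
    if np.any(dmin == dmax):
        bad = [table.names[j] for j in np.flatnonzero(dmin == dmax)]
        warnings.warn(
            f"constant feature(s) {bad}: mapped to midpoint (a+b)/2",
            UserWarning,
            stacklevel=2,
        )
    return NormalizationSpec(a, b, dmin, dmax)


def apply_normalization(table: FeatureTable, spec: NormalizationSpec) -> FeatureTable:
    """Rescale every feature with ``spec``; out-of-range values extrapolate
    linearly rather than being clipped."""
    if spec.d != table.d:
        raise ValueError(f"spec has {spec.d} features, table has {table.d}")
    span = np.where(spec.constant_mask, 1.0, spec.dmax - spec.dmin)
    scaled = spec.a + (spec.b - spec.a) * (table.features - spec.dmin) / span
    scaled[:, spec.constant_mask] = 0.5 * (spec.a + spec.b)
    return FeatureTable(scaled, table.labels, list(table.names))


def invert_normalization(table: FeatureTable, spec: NormalizationSpec) -> FeatureTable:
    """Inverse of :func:`apply_normalization` on non-constant features."""
    if spec.d != table.d:
        raise ValueError(f"spec has {spec.d} features, table has {table.d}")
    span = np.where(spec.constant_mask, 1.0, spec.dmax - spec.dmin)
    raw = spec.dmin + (table.features - spec.a) * span / (spec.b - spec.a)
    raw[:, spec.constant_mask] = spec.dmin[spec.constant_mask]
    return FeatureTable(raw, table.labels, list(table.names))


def shuffle_split(table: FeatureTable, ratio: float = 0.7, seed: int = 0) -> SplitPair:
    """Seeded random permutation followed by a head/tail split.

    The first ``floor(ratio * n)`` shuffled rows form the training table.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(table.n)
    n_train = int(np.floor(ratio * table.n))
    if n_train == 0 or n_train == table.n:
        raise ValueError("split leaves one side empty")
    return SplitPair(
        train=table.subset(perm[:n_train]),
        test=table.subset(perm[n_train:]),
        seed=seed,
        ratio=ratio,
    )


def generate_synthetic(spec: SyntheticSpec) -> FeatureTable:
    """Draw a synthetic Pima-like table according to ``spec``.

    Labels are Bernoulli(prevalence) mapped to ``{-1, +1}``; features come
    from class-shifted truncated normals (support ``[0, inf)``), and a
    ``label_flip`` fraction of labels is inverted at the end.  Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    y = np.where(rng.random(spec.n) < spec.prevalence, 1, -1)
    means = spec.base_mean + np.where(y[:, None] == 1, spec.effect, 0.0)
    if spec.noise_sd == 0:
        X = means.astype(float)
    else:
        # truncnorm parametrizes bounds in standard-deviation units
        lower = (0.0 - means) / spec.noise_sd
        X = stats.truncnorm.rvs(
            lower, np.inf, loc=means, scale=spec.noise_sd, random_state=rng
        )
    if spec.label_flip > 0:
        flip = rng.random(spec.n) < spec.label_flip
        y = np.where(flip, -y, y)
    return FeatureTable(X, y)


def read_csv(
    path,
    has_header: bool = True,
    label_column: str | int = -1,
) -> FeatureTable:
    """Load a numeric CSV into a :class:`FeatureTable`.

    The label column (by name or 0-based index, negative allowed) must be
    binary: either ``{0, 1}`` (remapped to ``{-1, +1}``) or already
    ``{-1, +1}``.  Missing values are an error.
    """
    df = pd.read_csv(path, header=0 if has_header else None)
    if not has_header:
        df.columns = [f"x{j}" for j in range(df.shape[1])]
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values are not supported")
    if isinstance(label_column, int):
        label_name = df.columns[label_column]
    else:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        label_name = label_column
    raw = df[label_name].to_numpy()
    values = set(np.unique(raw).tolist())
    if values <= {0, 1}:
        labels = np.where(raw == 1, 1, -1)
    elif values <= {-1, 1}:
        labels = raw.astype(int)
    else:
        raise ValueError(f"label column must be binary, got values {sorted(values)}")
    feats = df.drop(columns=[label_name])
    return FeatureTable(feats.to_numpy(dtype=float), labels, list(feats.columns))


def write_csv(table: FeatureTable, path, label_name: str = "label") -> None:
    """Write a table as CSV with a header; labels stored as ``{0, 1}``."""
    df = pd.DataFrame(table.features, columns=table.names)
    df[label_name] = (table.labels == 1).astype(int)
    df.to_csv(path, index=False)
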