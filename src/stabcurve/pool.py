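"""Data pools: loading tabular pools from CSV and generating synthetic pools.

A *pool* is the full dataset currently available, treated as a surrogate
population. All subsampled studies draw from it without replacement, which
simulates the measurement process of collecting a dataset of a given size.

Synthetic pools follow a linear-Gaussian design, ``y = X w + eps`` with
``X`` i.i.d. standard normal and ``eps ~ N(0, noise_sd^2)``.  Under this
design the best achievable test-set R² (the asymptote a consistent
regression model approaches as training data grows) is known in closed
form::

    R²_inf = V / (V + noise_sd²),   V = Σ w_i²

which makes the asymptote of a fitted learning curve directly checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DataPool",
    "SyntheticSpec",
    "PoolFileNotFoundError",
    "MissingTargetColumnError",
    "NonNumericDataError",
    "load_pool",
    "generate_pool",
    "asymptotic_r2",
]


class PoolFileNotFoundError(FileNotFoundError):
    """The CSV file for a data pool does not exist."""


class MissingTargetColumnError(KeyError):
    """The named target column is absent from the CSV header."""


class NonNumericDataError(ValueError):
    """A cell in the pool file could not be parsed as a number."""


@dataclass(frozen=True)
class DataPool:
    """Feature matrix plus numeric target vector.

    Rows are samples; columns of ``features`` are unitless covariates.
    Missing values are rejected at construction — the methodology assumes
    a clean pool and never imputes.
    """

    features: np.ndarray
    target: np.ndarray
    feature_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.target, dtype=float)
        if X.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if y.ndim != 1:
            raise ValueError("target must be a 1-D vector")
        if X.shape[0] != y.shape[0]:
            raise ValueError(
                f"feature rows ({X.shape[0]}) != target length ({y.shape[0]})"
            )
        if X.shape[0] < 1:
            raise ValueError("a pool needs at least 1 row")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise NonNumericDataError("pool contains missing or non-finite values")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "target", y)
        if not self.feature_names:
            object.__setattr__(
                self,
                "feature_names",
                tuple(f"x{i}" for i in range(X.shape[1])),
            )

    @property
    def sample_count(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def take(self, rows: np.ndarray) -> "DataPool":
        """Row-subset view (copy) of the pool, preserving row order given."""
        return DataPool(self.features[rows], self.target[rows], self.feature_names)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a linear-Gaussian synthetic pool (see module docstring)."""

    n_samples: int
    weight_vector: tuple[float, ...]
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "weight_vector", tuple(float(w) for w in self.weight_vector))
        if len(self.weight_vector) == 0:
            raise ValueError("weight_vector must be non-empty")

    @property
    def n_features(self) -> int:
        return len(self.weight_vector)


def load_pool(path, target_column: str) -> DataPool:
    """Read a CSV pool (header row, all-numeric cells) into a :class:`DataPool`.

    ``target_column`` names the response; every other column, in file order,
    becomes a feature.  Distinct errors are raised for a missing file, a
    missing column and non-numeric cells — the pool is never cleaned or
    imputed silently.
    """
    try:
        frame = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise PoolFileNotFoundError(str(path)) from exc
    if target_column not in frame.columns:
        raise MissingTargetColumnError(
            f"target column {target_column!r} not in {list(frame.columns)}"
        )
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.columns[numeric.isna().any()].tolist()
        raise NonNumericDataError(f"non-numeric cell(s) in column(s) {bad}")
    if len(numeric) < 2:
        raise ValueError("a pool file needs at least 2 rows")
    y = numeric[target_column].to_numpy(dtype=float)
    feats = numeric.drop(columns=[target_column])
    return DataPool(feats.to_numpy(dtype=float), y, tuple(feats.columns))


def generate_pool(spec: SyntheticSpec) -> DataPool:
    """Deterministically generate the linear-Gaussian pool described by *spec*.

    Identical specs (including the seed) yield bit-identical pools.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    w = np.asarray(spec.weight_vector)
    y = X @ w
    if spec.noise_sd > 0:
        y = y + spec.noise_sd * rng.standard_normal(spec.n_samples)
    return DataPool(X, y)


def asymptotic_r2(spec: SyntheticSpec) -> float:
    """Closed-form limit test-set R² of the generating model for *spec*.

    ``V/(V + sd²)`` with ``V = Σ w_i²``; this is the ground-truth accuracy a
    consistent regression model approaches with unbounded training data.
    """
    v = float(np.sum(np.square(spec.weight_vector)))
    denom = v + spec.noise_sd**2
    if denom == 0.0:
        return 1.0
    return v / denom
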