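"""Model adapters: the pluggable fit/score unit of the subsampling engine.

An adapter is anything with ``fit(X, y)`` and ``predict(X)`` (the sklearn
estimator contract).  The engine standardizes features (mean/sd fit on the
training split only) before handing data to the adapter, and scores both
splits with the coefficient of determination R².

Two optional fast paths let an adapter shortcut the generic per-repetition
loop, which matters because the adaptive stabilization loop may run an
accuracy evaluation tens of thousands of times per sample size:

``evaluate_batch(Xtr, ytr, Xte, yte)``
    Vectorized evaluation of a whole stack of repetitions at once.
    Inputs are 3-D ``(reps, rows, features)`` / 2-D ``(reps, rows)``
    arrays, already standardized per repetition; returns two ``(reps,)``
    arrays of train/test R².

``evaluate_pair(Xtr, ytr, Xte, yte, *, context)``
    Full control over a single repetition's scalar scores, bypassing
    fit/predict/R² entirely.  ``context`` is an :class:`EvalContext`
    identifying (sample-size percentage, instance, repetition).  This is
    the hook for mechanistic models or any custom scalar accuracy measure.

The two reference adapters are ordinary least squares and k-nearest-
neighbors regression; their batched paths are algebraically identical to
their sklearn single-fit counterparts (asserted in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Protocol, runtime_checkable

import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor

__all__ = [
    "EvalContext",
    "ModelAdapter",
    "OLSAdapter",
    "KNNAdapter",
    "SklearnAdapter",
    "batched_r2",
]

# chunk size for batched evaluation, bounds peak memory of distance matrices
_CHUNK = 128


class EvalContext(NamedTuple):
    """Identifies one repetition: size-ladder percentage, instance j, repetition i."""

    n_percent: float
    instance: int
    repetition: int


@runtime_checkable
class ModelAdapter(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray): ...

    def predict(self, X: np.ndarray) -> np.ndarray: ...


def batched_r2(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """R² along the last axis for stacked repetitions.

    Follows the sklearn convention for a constant truth vector: 1 when the
    predictions are exact, 0 otherwise.
    """
    sse = np.sum((y_true - y_pred) ** 2, axis=-1)
    sst = np.sum((y_true - y_true.mean(axis=-1, keepdims=True)) ** 2, axis=-1)
    out = np.empty(np.broadcast_shapes(sse.shape, sst.shape), dtype=float)
    ok = sst > 0
    out[ok] = 1.0 - sse[ok] / sst[ok]
    out[~ok] = np.where(sse[~ok] == 0, 1.0, 0.0)
    return out


@dataclass
class OLSAdapter:
    """Ordinary least squares regression (sklearn ``LinearRegression``).

    The batched path solves the per-repetition normal equations; features
    arrive standardized and hence centered, so the intercept is the training
    target mean and the coefficient system is ``(Xc'Xc) w = Xc' yc``.
    """

    def __post_init__(self) -> None:
        self._est = LinearRegression()

    def fit(self, X, y):
        self._est.fit(X, y)
        return self

    def predict(self, X):
        return self._est.predict(X)

    def evaluate_batch(self, Xtr, ytr, Xte, yte):
        ytr_mean = ytr.mean(axis=1, keepdims=True)
        yc = ytr - ytr_mean
        XtT = Xtr.transpose(0, 2, 1)
        gram = XtT @ Xtr
        rhs = XtT @ yc[..., None]
        try:
            coef = np.linalg.solve(gram, rhs)
        except np.linalg.LinAlgError:
            # rank-deficient repetition: minimum-norm solution, as lstsq would give
            coef = np.linalg.pinv(gram) @ rhs
        pred_tr = (Xtr @ coef)[..., 0] + ytr_mean
        pred_te = (Xte @ coef)[..., 0] + ytr_mean
        return batched_r2(ytr, pred_tr), batched_r2(yte, pred_te)


@dataclass
class KNNAdapter:
    """k-nearest-neighbors regression (sklearn ``KNeighborsRegressor``).

    ``n_neighbors`` is clipped to the training-set size when a subsample is
    smaller than the requested neighborhood, so small sample-ladder sizes
    degrade to a pool-mean predictor instead of failing.
    """

    n_neighbors: int = 25

    def fit(self, X, y):
        k = min(self.n_neighbors, X.shape[0])
        self._est = KNeighborsRegressor(n_neighbors=k)
        self._est.fit(X, y)
        return self

    def predict(self, X):
        return self._est.predict(X)

    def evaluate_batch(self, Xtr, ytr, Xte, yte):
        reps = Xtr.shape[0]
        k = min(self.n_neighbors, Xtr.shape[1])
        acc_tr = np.empty(reps)
        acc_te = np.empty(reps)
        for lo in range(0, reps, _CHUNK):
            sl = slice(lo, lo + _CHUNK)
            a, b = Xtr[sl], Xte[sl]
            acc_tr[sl] = batched_r2(ytr[sl], self._knn_mean(a, a, ytr[sl], k))
            acc_te[sl] = batched_r2(yte[sl], self._knn_mean(a, b, ytr[sl], k))
        return acc_tr, acc_te

    @staticmethod
    def _knn_mean(train, query, ytr, k):
        # squared euclidean distances (reps, n_query, n_train)
        d2 = (
            (query * query).sum(axis=-1)[:, :, None]
            - 2.0 * (query @ train.transpose(0, 2, 1))
            + (train * train).sum(axis=-1)[:, None, :]
        )
        idx = np.argpartition(d2, k - 1, axis=-1)[..., :k]
        return np.take_along_axis(ytr[:, None, :], idx, axis=-1).mean(axis=-1)


@dataclass
class SklearnAdapter:
    """Wrap any sklearn-style regressor as an adapter (no fast path)."""

    estimator: object

    def fit(self, X, y):
        from sklearn.base import clone

        self._est = clone(self.estimator)
        self._est.fit(X, y)
        return self

    def predict(self, X):
        return self._est.predict(X)
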