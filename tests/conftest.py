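"""Shared fixtures: tiny pools and instrumented adapters for loop contracts."""

from __future__ import annotations

import numpy as np
import pytest

import stabcurve as sc


class ConstantAccuracyAdapter:
    """Reports the same accuracy for every repetition (zero-variance distributions)."""

    def __init__(self, acc: float = 0.5):
        self.acc = acc

    def evaluate_pair(self, Xtr, ytr, Xte, yte, *, context):
        return self.acc, self.acc


class StreamAccuracyAdapter:
    """Deterministic pseudo-random accuracy keyed by (n, j, i).

    The accuracy stream is a pure function of the repetition coordinates,
    independent of call order and of any study tolerance — the reference
    instrument for monotone-effort and append-only contracts.
    """

    def __init__(self, seed: int = 0, scale: float = 0.05, loc: float = 0.5):
        self.seed, self.scale, self.loc = seed, scale, loc

    def _value(self, context, which):
        key = (self.seed, int(context.n_percent * 1000), context.instance,
               context.repetition, which)
        rng = np.random.default_rng(np.random.SeedSequence(abs(hash(key)) % 2**63))
        return self.loc + self.scale * rng.standard_normal()

    def evaluate_pair(self, Xtr, ytr, Xte, yte, *, context):
        return self._value(context, 0), self._value(context, 1)


class UniformAccuracyAdapter(StreamAccuracyAdapter):
    """I.i.d. uniform(0,1) accuracies — never stabilizes under a tiny tolerance."""

    def _value(self, context, which):
        key = (self.seed, int(context.n_percent * 1000), context.instance,
               context.repetition, which)
        rng = np.random.default_rng(np.random.SeedSequence(abs(hash(key)) % 2**63))
        return float(rng.random())


class TrainMeanAdapter:
    """Predicts the training-target mean everywhere (non-informative model)."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(X.shape[0], self.mean_)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_pool(rng):
    """60-row, 3-feature pool with moderate linear signal."""
    X = rng.standard_normal((60, 3))
    y = X @ np.array([1.0, -0.5, 0.25]) + 0.8 * rng.standard_normal(60)
    return sc.DataPool(X, y)


@pytest.fixture
def noiseless_pool():
    """Exactly linear pool: any consistent linear fit scores R² = 1."""
    return sc.generate_pool(
        sc.SyntheticSpec(n_samples=80, weight_vector=(1.0, 1.0), noise_sd=0.0, seed=1)
    )


@pytest.fixture
def constant_adapter():
    return ConstantAccuracyAdapter(0.5)


@pytest.fixture
def quick_config():
    return sc.StudyConfig(
        size_ladder_S=(50.0, 100.0),
        m_instances=2,
        k0_base_reps=10,
        tolerance=0.5,
        master_seed=7,
    )
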