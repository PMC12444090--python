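"""Model-free statistic mode: stabilize a test statistic's sampling distribution.

For planning studies around a test statistic rather than a model (e.g. the
mean of a biomarker under treatment, feeding an effect size into a power
analysis), no train/test split is needed.  Each repetition draws ``d_n``
rows from the pool and partitions them into ``m`` equally large
sub-samples (remainder rows are dropped); the statistic evaluated on
sub-sample ``j`` populates instance ``j``'s distribution.  The adaptive
tolerance loop — exit condition, k0 increment, determinism — is the very
code path used for model accuracies, with a single split label ``"stat"``.

Comparing two pools (say treated vs. untreated) via
:func:`effect_difference` yields the stabilized difference of means with
its percentile spread, the effect-strength input of a power calculation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .pool import DataPool
from .sampler import (
    AccuracyStore,
    StabilizedSize,
    StudyConfig,
    _adaptive_loop,
    _stream,
    _ARM_STAT,
    subsample_size,
)

__all__ = [
    "STATISTIC_REGISTRY",
    "StatisticSpec",
    "LadderMismatchError",
    "stabilize_statistic",
    "run_statistic_study",
    "effect_difference",
]

#: Built-in scalar statistics; extend by registering name -> callable.
STATISTIC_REGISTRY: dict[str, Callable[[np.ndarray], float]] = {
    "mean": np.mean,
    "median": np.median,
    "std": lambda v: np.std(v, ddof=1),
}


class LadderMismatchError(ValueError):
    """Two statistic studies cannot be differenced: their ladders differ."""


@dataclass(frozen=True)
class StatisticSpec:
    """Names the scalar statistic to stabilize and the column it acts on.

    ``column=None`` (default) applies the statistic to the pool's target
    vector; a feature name selects that feature column instead.
    """

    statistic_name: str = "mean"
    column: str | None = None

    def values_from(self, pool: DataPool) -> np.ndarray:
        if self.column is None:
            return pool.target
        if self.column in pool.feature_names:
            return pool.features[:, pool.feature_names.index(self.column)]
        raise ValueError(
            f"column {self.column!r} not among features {pool.feature_names}"
        )

    def resolve(self) -> Callable[[np.ndarray], float]:
        try:
            return STATISTIC_REGISTRY[self.statistic_name]
        except KeyError:
            raise ValueError(
                f"unknown statistic {self.statistic_name!r}; "
                f"known: {sorted(STATISTIC_REGISTRY)}"
            ) from None


def stabilize_statistic(
    pool: DataPool,
    n_percent: float,
    spec: StatisticSpec,
    config: StudyConfig,
    store: AccuracyStore | None = None,
) -> StabilizedSize:
    """Adaptive stabilization of a statistic's distribution at one ladder entry.

    One repetition = one draw of ``d_n`` rows split into ``m`` sub-samples
    of ``floor(d_n/m)`` rows each (one per instance j; the remainder of the
    draw is dropped).
    """
    stat = spec.resolve()
    column = spec.values_from(pool)
    d_n = subsample_size(pool.sample_count, n_percent)
    m = config.m_instances
    if d_n < m:
        raise ValueError(f"d_n={d_n} smaller than m={m}: cannot form sub-samples")
    sub = d_n // m

    def block_eval(block: int, k: int) -> dict[tuple[int, str], np.ndarray]:
        rng = _stream(config.master_seed, n_percent, 0, block, _ARM_STAT)
        vals = np.empty((m, k))
        for r in range(k):
            idx = rng.choice(pool.sample_count, size=d_n, replace=False)
            y = column[idx]
            for j in range(m):
                vals[j, r] = stat(y[j * sub : (j + 1) * sub])
        return {(j + 1, "stat"): vals[j] for j in range(m)}

    values, k_n, converged, summaries = _adaptive_loop(
        block_eval, config, ("stat",), label=f"n={n_percent}% stat"
    )
    if store is not None:
        for (j, sp), arr in values.items():
            store.append(n_percent, j, sp, arr)
        store.k_n[float(n_percent)] = k_n
    return StabilizedSize(
        n_percent=float(n_percent), d_n=d_n, train_size=None, test_size=None,
        final_k_n=k_n, summaries=summaries, converged=converged, sub_size=sub,
    )


def run_statistic_study(
    pool: DataPool,
    spec: StatisticSpec,
    config: StudyConfig,
    store: AccuracyStore | None = None,
) -> list[StabilizedSize]:
    """Stabilize the statistic at every ladder entry, ascending."""
    return [stabilize_statistic(pool, n, spec, config, store) for n in config.size_ladder_S]


def effect_difference(
    result_a: list[StabilizedSize], result_b: list[StabilizedSize]
) -> pd.DataFrame:
    """Per-size difference of stabilized mean statistics between two pools.

    Returns a tidy frame with, per ladder entry, the difference of the mean
    characteristics (averaged over instances) and each study's q25-q75
    spread — the raw material for an effect-strength estimate.
    """
    ladder_a = [r.n_percent for r in result_a]
    ladder_b = [r.n_percent for r in result_b]
    if ladder_a != ladder_b:
        raise LadderMismatchError(f"ladders differ: {ladder_a} vs {ladder_b}")
    rows = []
    for ra, rb in zip(result_a, result_b):
        js = sorted({j for j, _ in ra.summaries})
        mean_a = float(np.mean([ra.summaries[(j, "stat")].mean for j in js]))
        mean_b = float(np.mean([rb.summaries[(j, "stat")].mean for j in js]))
        width_a = float(np.mean(
            [ra.summaries[(j, "stat")].q75 - ra.summaries[(j, "stat")].q25 for j in js]
        ))
        width_b = float(np.mean(
            [rb.summaries[(j, "stat")].q75 - rb.summaries[(j, "stat")].q25 for j in js]
        ))
        rows.append(
            dict(n_percent=ra.n_percent, sub_size=ra.sub_size,
                 difference=mean_a - mean_b, width_a=width_a, width_b=width_b)
        )
    return pd.DataFrame(rows)
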