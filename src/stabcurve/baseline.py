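"""Shuffled-output baseline: where does real model learning start?

A model trained on targets that were randomly permuted within the training
split can only reproduce noise; comparing its test accuracies with those of
the genuinely trained model tells whether, at a given sample size, the
relations learned from training data carry over to unseen data at all.
The smallest ladder size at which the genuine model is significantly better
(one-sided Mann–Whitney U, for every instance j) is the minimum learning
size ``n0``.  Sizes below it carry no usable signal and can optionally be
excluded from learning-curve fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import mannwhitneyu

from .pool import DataPool
from .sampler import AccuracyStore, DistSummary, StabilizedSize, StudyConfig, stabilize_size

__all__ = ["N0_NOT_FOUND", "BaselineResult", "shuffle_targets", "mwu_one_sided", "determine_n0"]

#: Sentinel for "no ladder size showed significant learning".
N0_NOT_FOUND = None


@dataclass(frozen=True)
class BaselineResult:
    """Outcome of the shuffled-baseline scan over the size ladder.

    ``n0_percent`` is the smallest qualifying ladder percentage, or
    :data:`N0_NOT_FOUND` when no size passed (the sentinel state in which
    the scan starts, initialised above 100%).
    """

    n0_percent: float | None
    per_size_p_values: Mapping[tuple[float, int], float]
    shuffled_summaries: Mapping[tuple[float, int, str], DistSummary]
    shuffled_sizes: tuple[StabilizedSize, ...] = ()
    significance_level: float = 0.05


def shuffle_targets(train: DataPool, rng: np.random.Generator) -> DataPool:
    """Return the pool with its target vector uniformly permuted.

    Features are untouched and the multiset of target values is preserved
    exactly — only the feature/target pairing is destroyed.
    """
    perm = rng.permutation(train.sample_count)
    return DataPool(train.features, train.target[perm], train.feature_names)


def mwu_one_sided(greater_sample, lesser_sample) -> float:
    """One-sided Mann–Whitney U p-value.

    Tests the null of a common distribution against the alternative that
    ``greater_sample`` is stochastically larger.  Exact enumeration for
    small tie-free samples, normal approximation with tie correction
    otherwise (scipy's ``method="auto"`` policy).
    """
    greater_sample = np.asarray(greater_sample, dtype=float)
    lesser_sample = np.asarray(lesser_sample, dtype=float)
    if greater_sample.size == 0 or lesser_sample.size == 0:
        raise ValueError("both samples must be nonempty")
    res = mannwhitneyu(greater_sample, lesser_sample, alternative="greater", method="auto")
    return float(res.pvalue)


def determine_n0(
    pool: DataPool,
    adapter,
    config: StudyConfig,
    store: AccuracyStore,
    *,
    significance_level: float = 0.05,
) -> BaselineResult:
    """Scan the ladder upward for the minimum learning size ``n0``.

    For each ladder size (ascending, while n0 is still unknown) the
    shuffled-output accuracy distributions are stabilized with the same
    adaptive machinery as the main study, then for every instance j the
    genuine test accuracies are compared against the shuffled ones with a
    one-sided Mann–Whitney U test.  A size qualifies when p < the
    significance level for *all* j and the genuine mean test accuracy
    exceeds the shuffled one for all j; the first qualifying size is n0.

    Requires the main study's accuracies for the same config to be present
    in ``store`` (run :func:`~stabcurve.sampler.run_study` first).
    """
    if not 0.0 < significance_level < 1.0:
        raise ValueError("significance_level must be in (0, 1)")
    p_values: dict[tuple[float, int], float] = {}
    shuffled_summaries: dict[tuple[float, int, str], DistSummary] = {}
    shuffled_sizes: list[StabilizedSize] = []
    n0 = N0_NOT_FOUND
    for n in config.size_ladder_S:
        if n0 is not None:
            break  # scanning ascends; the first qualifying size is final
        res = stabilize_size(pool, n, adapter, config, store, shuffle=True)
        shuffled_sizes.append(res)
        qualifies = True
        for j in range(1, config.m_instances + 1):
            genuine = store.get(n, j, "te")
            shuffled = store.get(n, j, "te", shuffled=True)
            p = mwu_one_sided(genuine, shuffled)
            p_values[(float(n), j)] = p
            for sp in ("tr", "te"):
                shuffled_summaries[(float(n), j, sp)] = res.summaries[(j, sp)]
            if not (p < significance_level and genuine.mean() > shuffled.mean()):
                qualifies = False
        if qualifies:
            n0 = float(n)
    return BaselineResult(
        n0_percent=n0,
        per_size_p_values=p_values,
        shuffled_summaries=shuffled_summaries,
        shuffled_sizes=tuple(shuffled_sizes),
        significance_level=significance_level,
    )
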