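"""Adaptive subsampling engine: stabilized accuracy distributions per sample size.

For each percentage ``n`` on the size ladder the engine repeatedly

1. draws ``d_n`` rows (``n`` percent of the pool, without replacement),
2. splits them into a training fraction ``c`` and a test remainder,
3. standardizes features on the training split, fits the model adapter and
   records train/test R²,

building ``m`` parallel accuracy distributions (instances ``j = 1..m``).
Repetitions grow in blocks of ``k0`` per instance until the four
distribution characteristics — mean, median, 25th and 75th percentile —
agree pairwise across instances within a tolerance, on both the train and
test distributions.  The repetition count at which this happens, ``k_n``,
is therefore chosen adaptively per sample size: distributions with large
sampling spread get more repetitions, cheap stable ones fewer, and the
final characteristics no longer depend on the luck of a single run beyond
the chosen tolerance.

Randomness is organised as one independent deterministic stream per
(sample size, instance, repetition block, arm), all derived from the
single master seed.  Results are therefore reproducible bit-for-bit,
independent of execution order, and extending a run appends repetitions
without perturbing earlier ones.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.metrics import r2_score
from sklearn.preprocessing import StandardScaler

from .adapters import EvalContext, batched_r2
from .pool import DataPool

__all__ = [
    "CHARACTERISTICS",
    "StudyConfig",
    "ConfigError",
    "DegenerateSplitError",
    "AdapterEvaluationError",
    "StabilizationCapWarning",
    "DistSummary",
    "StabilizedSize",
    "AccuracyStore",
    "subsample_size",
    "draw_subsample",
    "split_train_test",
    "evaluate_once",
    "summarize",
    "characteristics_similar",
    "stabilize_size",
    "run_study",
    "fixed_reps_study",
]

log = logging.getLogger("stabcurve")

CHARACTERISTICS = ("mean", "median", "q25", "q75")

# arm codes keying independent random streams
_ARM_MAIN = 0
_ARM_SHUFFLED = 1
_ARM_STAT = 2


class ConfigError(ValueError):
    """Invalid study configuration; message lists every offending field."""


class DegenerateSplitError(ValueError):
    """A train/test split would leave one side empty."""


class AdapterEvaluationError(RuntimeError):
    """Model adapter failed; message carries (n, instance, repetition) context."""


class StabilizationCapWarning(UserWarning):
    """The repetition cap was reached before the tolerances were met."""


@dataclass(frozen=True)
class StudyConfig:
    """All parameters of an adaptive subsampling study.

    Parameters
    ----------
    split_fraction_c:
        Training fraction of each subsample, 0 < c < 1.
    size_ladder_S:
        Strictly ascending pool percentages in (0, 100] at which studies run.
    m_instances:
        Number of parallel accuracy distributions compared for stability (>= 2).
    k0_base_reps:
        Block size: the minimum repetition count and the increment added to
        ``k_n`` after each failed similarity round.
    tolerance:
        Maximum allowed absolute pairwise difference between corresponding
        characteristics of the instances; a scalar applied to all four
        characteristics, or a mapping {characteristic: tolerance}.
    max_reps_cap:
        Safety valve: stop (converged=False) rather than let ``k_n`` exceed
        this. Defaults to 100 * k0.
    n0_initial:
        Sentinel (> 100) for the minimum-learning-size percentage before the
        shuffled baseline has identified one.
    master_seed:
        Single seed from which every random stream derives.
    """

    split_fraction_c: float = 0.7
    size_ladder_S: tuple[float, ...] = tuple(float(s) for s in range(10, 101, 10))
    m_instances: int = 2
    k0_base_reps: int = 300
    tolerance: float | Mapping[str, float] = 0.005
    max_reps_cap: int | None = None
    n0_initial: int = 101
    master_seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if not (0.0 < self.split_fraction_c < 1.0):
            problems.append("split_fraction_c must be in (0, 1)")
        S = tuple(float(s) for s in self.size_ladder_S)
        object.__setattr__(self, "size_ladder_S", S)
        if not S:
            problems.append("size_ladder_S must be non-empty")
        elif not all(0.0 < s <= 100.0 for s in S):
            problems.append("size_ladder_S entries must be in (0, 100]")
        elif any(b <= a for a, b in zip(S, S[1:])):
            problems.append("size_ladder_S must be strictly ascending")
        if self.m_instances < 2:
            problems.append("m_instances must be >= 2")
        if self.k0_base_reps < 1:
            problems.append("k0_base_reps must be >= 1")
        for name, tol in self._tolerance_items():
            if name not in CHARACTERISTICS:
                problems.append(f"unknown characteristic {name!r} in tolerance")
            elif not tol > 0:
                problems.append(f"tolerance[{name}] must be > 0")
        if self.max_reps_cap is None:
            object.__setattr__(self, "max_reps_cap", 100 * self.k0_base_reps)
        if self.max_reps_cap < 1:
            problems.append("max_reps_cap must be >= 1")
        if self.n0_initial <= 100:
            problems.append("n0_initial must be > 100")
        if problems:
            raise ConfigError("; ".join(problems))

    def _tolerance_items(self):
        if isinstance(self.tolerance, Mapping):
            return tuple(self.tolerance.items())
        return tuple((c, float(self.tolerance)) for c in CHARACTERISTICS)

    def tolerance_for(self, characteristic: str) -> float:
        if isinstance(self.tolerance, Mapping):
            return float(self.tolerance[characteristic])
        return float(self.tolerance)

    def validate_for_pool(self, pool_size: int) -> None:
        """Check that every ladder entry yields non-empty train and test sets."""
        problems = []
        for n in self.size_ladder_S:
            d_n = subsample_size(pool_size, n)
            if d_n > pool_size:
                problems.append(f"ladder entry {n}% exceeds the pool size")
                continue
            n_tr = math.floor(self.split_fraction_c * d_n)
            if n_tr < 1 or d_n - n_tr < 1:
                problems.append(
                    f"ladder entry {n}% gives d_n={d_n}, degenerate split under c={self.split_fraction_c}"
                )
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass(frozen=True)
class DistSummary:
    """The four stabilized characteristics of one accuracy distribution."""

    mean: float
    median: float
    q25: float
    q75: float
    count: int


@dataclass(frozen=True)
class StabilizedSize:
    """Outcome of the adaptive loop at one ladder entry.

    ``summaries`` maps ``(instance j, split)`` to a :class:`DistSummary`,
    where split is ``"tr"``/``"te"`` for model studies and ``"stat"`` for
    the model-free statistic mode (there ``sub_size`` is the size of each
    of the m equal sub-samples and train/test sizes are absent).
    """

    n_percent: float
    d_n: int
    train_size: int | None
    test_size: int | None
    final_k_n: int
    summaries: Mapping[tuple[int, str], DistSummary]
    converged: bool
    sub_size: int | None = None


class AccuracyStore:
    """Append-only record of every accuracy value produced by a study.

    Indexed by (ladder percentage n, instance j, split); the shuffled-
    baseline arm is held separately with the same structure.  Values are
    never recomputed or discarded when the repetition count grows.
    """

    def __init__(self) -> None:
        self.values: dict[float, dict[int, dict[str, np.ndarray]]] = {}
        self.shuffled_values: dict[float, dict[int, dict[str, np.ndarray]]] = {}
        self.k_n: dict[float, int] = {}
        self.shuffled_k_n: dict[float, int] = {}

    def _tree(self, shuffled: bool):
        return self.shuffled_values if shuffled else self.values

    def append(self, n: float, j: int, split: str, vals: np.ndarray, *, shuffled: bool = False) -> None:
        slot = self._tree(shuffled).setdefault(float(n), {}).setdefault(int(j), {})
        prev = slot.get(split)
        vals = np.asarray(vals, dtype=float)
        slot[split] = vals.copy() if prev is None else np.concatenate([prev, vals])

    def get(self, n: float, j: int, split: str, *, shuffled: bool = False) -> np.ndarray:
        return self._tree(shuffled)[float(n)][int(j)][split]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def subsample_size(pool_size: int, n_percent: float) -> int:
    """Number of rows in an ``n_percent`` draw: round half up, floored at 2."""
    if not 0.0 < n_percent <= 100.0:
        raise ValueError("n_percent must be in (0, 100]")
    return max(2, math.floor(n_percent / 100.0 * pool_size + 0.5))


def draw_subsample(pool: DataPool, d_n: int, rng: np.random.Generator) -> DataPool:
    """Draw ``d_n`` rows uniformly without replacement, in randomized order."""
    if not 2 <= d_n <= pool.sample_count:
        raise ValueError(f"d_n={d_n} out of range [2, {pool.sample_count}]")
    idx = rng.choice(pool.sample_count, size=d_n, replace=False)
    return pool.take(idx)


def split_train_test(sub: DataPool, c: float, rng: np.random.Generator) -> tuple[DataPool, DataPool]:
    """Random partition into floor(c*d_n) training rows and the test remainder."""
    d_n = sub.sample_count
    n_tr = math.floor(c * d_n)
    if n_tr < 1 or d_n - n_tr < 1:
        raise DegenerateSplitError(f"c={c} on {d_n} rows leaves an empty side")
    perm = rng.permutation(d_n)
    return sub.take(perm[:n_tr]), sub.take(perm[n_tr:])


def evaluate_once(adapter, train: DataPool, test: DataPool) -> tuple[float, float]:
    """Standardize on train, fit the adapter, score R² on both splits."""
    scaler = StandardScaler().fit(train.features)
    Xtr = scaler.transform(train.features)
    Xte = scaler.transform(test.features)
    adapter.fit(Xtr, train.target)
    acc_tr = float(r2_score(train.target, adapter.predict(Xtr)))
    acc_te = float(r2_score(test.target, adapter.predict(Xte)))
    return acc_tr, acc_te


def summarize(values: Sequence[float]) -> DistSummary:
    """Mean, median and interpolated 25th/75th percentiles of a distribution."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty distribution")
    q25, med, q75 = np.percentile(arr, [25.0, 50.0, 75.0])
    return DistSummary(float(arr.mean()), float(med), float(q25), float(q75), int(arr.size))


def characteristics_similar(
    sums: Sequence[DistSummary], tolerance: float | Mapping[str, float]
) -> bool:
    """True iff every characteristic agrees pairwise across instances within tolerance."""
    if len(sums) < 2:
        raise ValueError("need at least two summaries to compare")
    return _worst_excess(sums, tolerance) <= 0.0


def _worst_excess(sums, tolerance) -> float:
    """Largest (pairwise difference - tolerance) over all characteristics."""
    worst = -math.inf
    for char in CHARACTERISTICS:
        tol = tolerance[char] if isinstance(tolerance, Mapping) else float(tolerance)
        vals = [getattr(s, char) for s in sums]
        worst = max(worst, (max(vals) - min(vals)) - tol)
    return worst


# ---------------------------------------------------------------------------
# random streams
# ---------------------------------------------------------------------------

def _stream(master_seed: int, n_percent: float, j: int, block: int, arm: int) -> np.random.Generator:
    """Independent deterministic generator for one (size, instance, block, arm)."""
    n_key = int(round(float(n_percent) * 1_000_000))
    entropy = int(master_seed) % (2**63)
    return np.random.default_rng(np.random.SeedSequence(entropy, spawn_key=(n_key, j, block, arm)))


# ---------------------------------------------------------------------------
# batched evaluation of one repetition block
# ---------------------------------------------------------------------------

def _draw_indices(rng: np.random.Generator, k: int, N: int, d_n: int) -> np.ndarray:
    """``k`` uniform without-replacement draws of ``d_n`` from ``N``, random order.

    Each row gets i.i.d. random keys; the ``d_n`` smallest keys form the
    draw (a uniform subset) and sorting those keys gives a uniform order —
    one vectorized operation instead of ``k`` generator calls.
    """
    keys = rng.random((k, N))
    part = np.argpartition(keys, d_n - 1, axis=1)[:, :d_n]
    order = np.argsort(np.take_along_axis(keys, part, axis=1), axis=1)
    return np.take_along_axis(part, order, axis=1)


def _model_block(
    pool: DataPool,
    d_n: int,
    n_tr: int,
    adapter,
    rng: np.random.Generator,
    k: int,
    *,
    n_percent: float,
    instance: int,
    start_rep: int,
    shuffle: bool = False,
) -> dict[str, np.ndarray]:
    """Evaluate ``k`` draw/split/fit/score repetitions for one instance."""
    idx = _draw_indices(rng, k, pool.sample_count, d_n)
    Xtr = pool.features[idx[:, :n_tr]]
    ytr = pool.target[idx[:, :n_tr]]
    Xte = pool.features[idx[:, n_tr:]]
    yte = pool.target[idx[:, n_tr:]]
    if shuffle:
        perm = np.argsort(rng.random((k, n_tr)), axis=1)
        ytr = np.take_along_axis(ytr, perm, axis=1)
    # per-repetition standardization, fit on the training split only
    mu = Xtr.mean(axis=1, keepdims=True)
    xc = Xtr - mu
    sd = np.sqrt((xc * xc).mean(axis=1, keepdims=True))
    sd[sd == 0.0] = 1.0
    Xtr = xc / sd
    Xte = (Xte - mu) / sd

    try:
        if hasattr(adapter, "evaluate_batch"):
            acc_tr, acc_te = adapter.evaluate_batch(Xtr, ytr, Xte, yte)
        elif hasattr(adapter, "evaluate_pair"):
            acc_tr = np.empty(k)
            acc_te = np.empty(k)
            for r in range(k):
                ctx = EvalContext(n_percent, instance, start_rep + r)
                acc_tr[r], acc_te[r] = adapter.evaluate_pair(
                    Xtr[r], ytr[r], Xte[r], yte[r], context=ctx
                )
        else:
            pred_tr = np.empty_like(ytr)
            pred_te = np.empty_like(yte)
            for r in range(k):
                adapter.fit(Xtr[r], ytr[r])
                pred_tr[r] = adapter.predict(Xtr[r])
                pred_te[r] = adapter.predict(Xte[r])
            acc_tr = batched_r2(ytr, pred_tr)
            acc_te = batched_r2(yte, pred_te)
    except Exception as exc:  # re-raise with study coordinates
        raise AdapterEvaluationError(
            f"adapter failed at n={n_percent}%, instance j={instance}, "
            f"repetitions {start_rep}..{start_rep + k - 1}: {exc}"
        ) from exc
    return {"tr": np.asarray(acc_tr, float), "te": np.asarray(acc_te, float)}


# ---------------------------------------------------------------------------
# the adaptive loop
# ---------------------------------------------------------------------------

def _merge_sorted(big: np.ndarray | None, new_sorted: np.ndarray) -> np.ndarray:
    """Linear-time merge of a sorted block into a sorted accumulator."""
    if big is None:
        return new_sorted
    pos = np.searchsorted(big, new_sorted) + np.arange(new_sorted.size)
    out = np.empty(big.size + new_sorted.size)
    mask = np.ones(out.size, dtype=bool)
    mask[pos] = False
    out[pos] = new_sorted
    out[mask] = big
    return out


def _quantile_sorted(s: np.ndarray, p: float) -> float:
    """Linear-interpolation quantile of an already-sorted array (O(1))."""
    h = (s.size - 1) * p
    lo = int(h)
    frac = h - lo
    if frac == 0.0:
        return float(s[lo])
    return float(s[lo] + (s[lo + 1] - s[lo]) * frac)


def _adaptive_loop(
    block_eval: Callable[[int, int], dict[tuple[int, str], np.ndarray]],
    config: StudyConfig,
    splits: tuple[str, ...],
    *,
    label: str = "",
) -> tuple[dict[tuple[int, str], np.ndarray], int, bool, dict[tuple[int, str], DistSummary]]:
    """Grow repetitions in blocks of k0 until all characteristics stabilize.

    ``block_eval(block_index, k)`` returns ``k`` new accuracies for every
    (instance, split) pair; previously returned values are kept untouched
    (append-only), so the loop only ever adds information.  Distribution
    characteristics are tracked incrementally — running sums for the mean,
    merge-maintained sorted arrays for the percentiles — so a similarity
    round costs O(current block), not O(accumulated repetitions).
    """
    m, k0, cap = config.m_instances, config.k0_base_reps, config.max_reps_cap
    blocks: dict[tuple[int, str], list[np.ndarray]] = {}
    sums: dict[tuple[int, str], float] = {}
    sorted_vals: dict[tuple[int, str], np.ndarray | None] = {}
    k_n, block = 0, 0
    while True:
        new = block_eval(block, k0)
        for key, arr in new.items():
            blocks.setdefault(key, []).append(arr)
            sums[key] = sums.get(key, 0.0) + float(arr.sum())
            sorted_vals[key] = _merge_sorted(sorted_vals.get(key), np.sort(arr))
        k_n += k0
        block += 1
        summaries = {
            key: DistSummary(
                mean=sums[key] / k_n,
                median=_quantile_sorted(sorted_vals[key], 0.50),
                q25=_quantile_sorted(sorted_vals[key], 0.25),
                q75=_quantile_sorted(sorted_vals[key], 0.75),
                count=k_n,
            )
            for key in blocks
        }
        worst = max(
            _worst_excess([summaries[(j, sp)] for j in range(1, m + 1)], config.tolerance)
            for sp in splits
        )
        log.debug("%s k_n=%d worst tolerance excess=%.3g", label, k_n, worst)
        done = worst <= 0.0
        capped = not done and k_n + k0 > cap
        if capped:
            warnings.warn(
                f"{label or 'stabilization'}: repetition cap {cap} reached at k_n={k_n} "
                f"without meeting tolerances (worst excess {worst:.3g})",
                StabilizationCapWarning,
                stacklevel=3,
            )
        if done or capped:
            values = {key: np.concatenate(parts) for key, parts in blocks.items()}
            return values, k_n, done, summaries


def stabilize_size(
    pool: DataPool,
    n_percent: float,
    adapter,
    config: StudyConfig,
    store: AccuracyStore | None = None,
    *,
    shuffle: bool = False,
) -> StabilizedSize:
    """Run the adaptive repetition loop at one ladder entry.

    With ``shuffle=True`` the training targets of every repetition are
    randomly permuted before fitting — the no-signal baseline arm.
    """
    d_n = subsample_size(pool.sample_count, n_percent)
    if d_n > pool.sample_count:
        raise ValueError(f"{n_percent}% of the pool exceeds the pool size")
    n_tr = math.floor(config.split_fraction_c * d_n)
    n_te = d_n - n_tr
    if n_tr < 1 or n_te < 1:
        raise DegenerateSplitError(
            f"c={config.split_fraction_c} on d_n={d_n} leaves an empty split"
        )
    arm = _ARM_SHUFFLED if shuffle else _ARM_MAIN

    def block_eval(block: int, k: int) -> dict[tuple[int, str], np.ndarray]:
        out = {}
        for j in range(1, config.m_instances + 1):
            rng = _stream(config.master_seed, n_percent, j, block, arm)
            res = _model_block(
                pool, d_n, n_tr, adapter, rng, k,
                n_percent=n_percent, instance=j, start_rep=block * config.k0_base_reps,
                shuffle=shuffle,
            )
            for sp, arr in res.items():
                out[(j, sp)] = arr
        return out

    values, k_n, converged, summaries = _adaptive_loop(
        block_eval, config, ("tr", "te"),
        label=f"n={n_percent}%{' shuffled' if shuffle else ''}",
    )
    if store is not None:
        for (j, sp), arr in values.items():
            store.append(n_percent, j, sp, arr, shuffled=shuffle)
        if shuffle:
            store.shuffled_k_n[float(n_percent)] = k_n
        else:
            store.k_n[float(n_percent)] = k_n
    log.info(
        "n=%s%%: d_n=%d (train %d / test %d), k_n=%d, converged=%s",
        n_percent, d_n, n_tr, n_te, k_n, converged,
    )
    return StabilizedSize(
        n_percent=float(n_percent), d_n=d_n, train_size=n_tr, test_size=n_te,
        final_k_n=k_n, summaries=summaries, converged=converged,
    )


def run_study(
    pool: DataPool,
    adapter,
    config: StudyConfig,
    store: AccuracyStore | None = None,
) -> list[StabilizedSize]:
    """Stabilize every ladder entry, in ascending order.

    Fully reproducible from ``config.master_seed``; pass an
    :class:`AccuracyStore` to retain every individual accuracy value.
    """
    config.validate_for_pool(pool.sample_count)
    return [stabilize_size(pool, n, adapter, config, store) for n in config.size_ladder_S]


def fixed_reps_study(
    pool: DataPool,
    adapter,
    config: StudyConfig,
    reps: int,
    store: AccuracyStore | None = None,
) -> list[StabilizedSize]:
    """Non-adaptive comparator: exactly ``reps`` repetitions per instance.

    Identical pipeline, but the adaptive loop is replaced by a single fixed
    block.  The ``converged`` flag reports (informationally) whether the
    stabilization tolerances would have been met at that repetition count.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    config.validate_for_pool(pool.sample_count)
    results = []
    for n in config.size_ladder_S:
        d_n = subsample_size(pool.sample_count, n)
        n_tr = math.floor(config.split_fraction_c * d_n)
        values: dict[tuple[int, str], np.ndarray] = {}
        for j in range(1, config.m_instances + 1):
            rng = _stream(config.master_seed, n, j, 0, _ARM_MAIN)
            res = _model_block(
                pool, d_n, n_tr, adapter, rng, reps,
                n_percent=n, instance=j, start_rep=0,
            )
            for sp, arr in res.items():
                values[(j, sp)] = arr
                if store is not None:
                    store.append(n, j, sp, arr)
        if store is not None:
            store.k_n[float(n)] = reps
        summaries = {key: summarize(arr) for key, arr in values.items()}
        would_pass = all(
            characteristics_similar(
                [summaries[(j, sp)] for j in range(1, config.m_instances + 1)],
                config.tolerance,
            )
            for sp in ("tr", "te")
        )
        results.append(
            StabilizedSize(
                n_percent=float(n), d_n=d_n, train_size=n_tr, test_size=d_n - n_tr,
                final_k_n=reps, summaries=summaries, converged=would_pass,
            )
        )
    return results
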