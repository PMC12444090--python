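"""Power-law learning curves: fitting, extrapolation and sanity checks.

Each stabilized characteristic (mean, median, 25th/75th percentile) of the
accuracy distributions traces a curve against the split sample size
(``c*d_n`` training rows for the train split, ``(1-c)*d_n`` test rows for
the test split).  The curve family is the three-parameter power law

    f(d) = alpha * d**beta + gamma

whose asymptote ``gamma`` (for beta < 0) is the limit accuracy — the value
the model approaches with unbounded data.  Fits minimize the unweighted
sum of squared residuals: every point carries the same stabilization
tolerance by construction, so equal weights are the appropriate choice.
Inverting the fitted curve yields the sample size required for a target
accuracy; the 25th/75th-percentile pair yields an uncertainty width whose
sign change (percentile crossing) marks where the fitted curves stop being
trustworthy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit

from .sampler import CHARACTERISTICS, StabilizedSize

__all__ = [
    "UNREACHABLE",
    "CurvePoint",
    "PowerLawFit",
    "UnderdeterminedFitError",
    "ExtrapolationWarning",
    "build_curve_points",
    "fit_power_law",
    "predict_accuracy",
    "required_sample_size",
    "uncertainty_width",
    "percentile_crossing_check",
]

#: Sentinel returned when a target accuracy lies beyond the fitted asymptote.
UNREACHABLE = None


class UnderdeterminedFitError(ValueError):
    """Fewer than three curve points: the three-parameter fit is underdetermined."""


class ExtrapolationWarning(UserWarning):
    """A prediction was requested beyond the largest fitted sample size."""


@dataclass(frozen=True)
class CurvePoint:
    """One (sample size, characteristic value) point of a learning curve."""

    sample_count: int
    value: float

    def __post_init__(self) -> None:
        if self.sample_count < 1:
            raise ValueError("sample_count must be >= 1")


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted f(d) = alpha * d**beta + gamma for one characteristic curve.

    ``gamma`` is the d -> infinity limit when ``beta < 0``.  A constant
    input curve is reported as the degenerate fit (alpha=0, gamma=value)
    with ``beta_identifiable=False`` rather than silently inventing a rate.
    """

    alpha: float
    beta: float
    gamma: float
    split: str = "te"
    characteristic: str = "mean"
    instance_j: int = 1
    residual_sum_of_squares: float = float("nan")
    converged: bool = True
    beta_identifiable: bool = True
    x_min: float | None = None
    x_max: float | None = None


def _power_law(d, alpha, beta, gamma):
    return alpha * np.power(d, beta) + gamma


def build_curve_points(
    results: Sequence[StabilizedSize],
    split: Literal["tr", "te", "stat"],
    characteristic: str,
    instance_j: int,
    *,
    n0: float | None = None,
    exclusion_rule: Literal["below_n0", "at_or_above_n0"] = "below_n0",
) -> list[CurvePoint]:
    """Extract one characteristic's learning-curve points from a study.

    x is the training-set size for ``split="tr"``, the test-set size for
    ``"te"``, and the sub-sample size in statistic mode.  When ``n0`` is
    given, ladder entries are dropped according to ``exclusion_rule``:
    ``"below_n0"`` (default) removes the pre-learning sizes n < n0;
    ``"at_or_above_n0"`` is the literal alternative reading and removes
    n >= n0 instead.  At least three points must survive.
    """
    if characteristic not in CHARACTERISTICS:
        raise ValueError(f"unknown characteristic {characteristic!r}")
    points = []
    for res in results:
        if n0 is not None:
            if exclusion_rule == "below_n0" and res.n_percent < n0:
                continue
            if exclusion_rule == "at_or_above_n0" and res.n_percent >= n0:
                continue
        if split == "tr":
            x = res.train_size
        elif split == "te":
            x = res.test_size
        elif split == "stat":
            x = res.sub_size
        else:
            raise ValueError(f"unknown split {split!r}")
        summary = res.summaries[(instance_j, split)]
        points.append(CurvePoint(int(x), getattr(summary, characteristic)))
    if len(points) < 3:
        raise UnderdeterminedFitError(
            f"under-determined fit: {len(points)} point(s), need >= 3"
        )
    return points


def fit_power_law(
    points: Sequence[CurvePoint],
    *,
    split: str = "te",
    characteristic: str = "mean",
    instance_j: int = 1,
) -> PowerLawFit:
    """Least-squares fit of the power law to curve points (equal weights).

    Multi-start local optimization: gamma starts at the last observed
    value, alpha at (first - last), beta at each of {-0.25, -0.5, -1};
    the start with the smallest residual sum of squares wins.  beta's sign
    is unconstrained — training curves may rise or fall.
    """
    if len(points) < 3 or len({p.sample_count for p in points}) < 3:
        raise UnderdeterminedFitError("need >= 3 points with >= 3 distinct sample sizes")
    order = np.argsort([p.sample_count for p in points])
    x = np.asarray([points[i].sample_count for i in order], dtype=float)
    y = np.asarray([points[i].value for i in order], dtype=float)
    meta = dict(split=split, characteristic=characteristic, instance_j=instance_j,
                x_min=float(x.min()), x_max=float(x.max()))

    if np.ptp(y) == 0.0:
        return PowerLawFit(alpha=0.0, beta=float("nan"), gamma=float(y[0]),
                           residual_sum_of_squares=0.0, converged=True,
                           beta_identifiable=False, **meta)

    gamma0 = float(y[-1])
    alpha0 = float(y[0] - y[-1]) or float(np.ptp(y))
    best = None
    diagnostics = []
    for beta0 in (-0.25, -0.5, -1.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _power_law, x, y, p0=(alpha0, beta0, gamma0), maxfev=20000
                )
            ssr = float(np.sum((_power_law(x, *popt) - y) ** 2))
            if best is None or ssr < best[1]:
                best = (popt, ssr)
        except (RuntimeError, ValueError) as exc:
            diagnostics.append(f"start beta0={beta0}: {exc}")
    if best is None:
        return PowerLawFit(alpha=float("nan"), beta=float("nan"), gamma=float("nan"),
                           residual_sum_of_squares=float("nan"), converged=False, **meta)
    (alpha, beta, gamma), ssr = best
    return PowerLawFit(alpha=float(alpha), beta=float(beta), gamma=float(gamma),
                       residual_sum_of_squares=ssr, converged=True, **meta)


def predict_accuracy(fit: PowerLawFit, d: float) -> float:
    """Evaluate the fitted curve at sample size ``d``.

    Warns with :class:`ExtrapolationWarning` when ``d`` exceeds the largest
    fitted sample size.
    """
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    if d <= 0:
        raise ValueError("sample size must be positive")
    if fit.x_max is not None and d > fit.x_max:
        warnings.warn(
            f"predicting at d={d} beyond the largest fitted size {fit.x_max}: extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    if fit.alpha == 0.0:
        return float(fit.gamma)
    return float(fit.alpha * d**fit.beta + fit.gamma)


def required_sample_size(fit: PowerLawFit, target_value: float) -> float | None:
    """Invert the fitted curve: sample size at which it reaches ``target_value``.

    Returns ``((target - gamma)/alpha) ** (1/beta)``, or :data:`UNREACHABLE`
    (None) when the target lies on the far side of the asymptote gamma.
    """
    if not fit.converged:
        raise ValueError("cannot invert a non-converged fit")
    if fit.alpha == 0.0 or not fit.beta_identifiable or fit.beta == 0.0:
        raise ValueError("degenerate fit: the curve is constant and cannot be inverted")
    ratio = (target_value - fit.gamma) / fit.alpha
    if ratio <= 0.0:
        return UNREACHABLE
    return float(ratio ** (1.0 / fit.beta))


def uncertainty_width(fit_q25: PowerLawFit, fit_q75: PowerLawFit, d: float) -> float:
    """Predicted 75th-minus-25th-percentile spread at sample size ``d``.

    Negative widths are possible and meaningful — see
    :func:`percentile_crossing_check`.
    """
    if fit_q25.split != fit_q75.split or fit_q25.instance_j != fit_q75.instance_j:
        raise ValueError("q25/q75 fits must describe the same split and instance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        return predict_accuracy(fit_q75, d) - predict_accuracy(fit_q25, d)


def percentile_crossing_check(
    fit_q25: PowerLawFit, fit_q75: PowerLawFit, d_max_search: float
) -> float | None:
    """Smallest sample size at which the percentile curves cross, if any.

    Searches [smallest fitted size, ``d_max_search``].  A crossing (the
    25th-percentile curve overtaking the 75th) marks the region where the
    fitted curves can no longer be used reliably; if the width is already
    non-positive at the search start the curves are crossed everywhere in
    range and the start is reported.  Returns None when the width never
    changes sign.
    """
    if not (fit_q25.converged and fit_q75.converged):
        raise ValueError("both fits must be converged")
    starts = [v for v in (fit_q25.x_min, fit_q75.x_min) if v is not None]
    lo = max(1.0, min(starts)) if starts else 1.0
    if lo >= d_max_search:
        raise ValueError("d_max_search must exceed the smallest fitted sample size")

    def width(d):
        return uncertainty_width(fit_q25, fit_q75, d)

    if width(lo) <= 0.0:
        return float(lo)
    grid = np.geomspace(lo, d_max_search, num=512)
    w = np.array([width(g) for g in grid])
    crossings = np.nonzero(w[1:] * w[:-1] <= 0.0)[0]
    if crossings.size == 0:
        return None
    i = int(crossings[0])
    if w[i + 1] == 0.0:
        return float(grid[i + 1])
    return float(brentq(width, grid[i], grid[i + 1]))
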