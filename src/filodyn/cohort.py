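"""Cohort-level statistics for filopodium metrics.

Two-group comparisons (e.g. wild-type vs mutant mean speeds, or metrics at
different developmental stages) use the unpaired two-sided Student t-test
with pooled variance; Welch's unequal-variance variant is available behind a
flag.  Raw p-values are reported without multiple-testing correction.

Filopodia-count time courses across developmental stages (percent of pupal
development) are expressed relative to a baseline stage (baseline = 100%)
and summarised with ordinary least-squares second-order polynomial fits,
reported in the ``y = c0 + c1*x + c2*x**2`` convention.

Group means of inactivity support excluding zero-inactivity filopodia:
short-lived filopodia often have zero inactivity by construction (few
intervals, all moving), which deflates naive group means; excluding them
makes transient and stable filopodia comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import stats

__all__ = [
    "GroupComparison",
    "TimeCourse",
    "PolyFit",
    "t_test_unpaired",
    "group_mean_inactivity",
    "normalize_to_baseline",
    "fit_poly2",
    "poly_eval",
]


@dataclass(frozen=True)
class GroupComparison:
    """Result of an unpaired two-group comparison of one metric."""

    metric: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    sd_a: float
    sd_b: float
    t_stat: float
    df: float
    p_two_sided: float


@dataclass(frozen=True)
class TimeCourse:
    """Values (counts or percentages) along developmental stages.

    ``points`` are ``(stage_pct, value)`` pairs with strictly increasing
    stages; ``baseline_stage`` identifies the stage that maps to 100% after
    normalisation.
    """

    points: tuple[tuple[float, float], ...]
    baseline_stage: float


@dataclass(frozen=True)
class PolyFit:
    """Quadratic least-squares fit ``y = c0 + c1*x + c2*x**2``."""

    c0: float
    c1: float
    c2: float
    rss: float


def t_test_unpaired(
    a: Sequence[float],
    b: Sequence[float],
    *,
    metric: str = "",
    welch: bool = False,
) -> GroupComparison:
    """Two-sided unpaired t-test between two groups of values.

    Pooled-variance Student test by default (``df = n_a + n_b - 2``); Welch's
    test when ``welch`` is True.  Degenerate inputs with zero variance in
    both groups give ``t = 0, p = 1`` when the means are equal and raise
    otherwise.
    """
    xa = np.asarray(list(a), dtype=float)
    xb = np.asarray(list(b), dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(xa).all() and np.isfinite(xb).all()):
        raise ValueError("groups must contain only finite values")
    mean_a, mean_b = float(xa.mean()), float(xb.mean())
    sd_a = float(xa.std(ddof=1))
    sd_b = float(xb.std(ddof=1))
    n_a, n_b = int(xa.size), int(xb.size)
    if sd_a == 0.0 and sd_b == 0.0:
        if mean_a == mean_b:
            df = float(n_a + n_b - 2)
            return GroupComparison(
                metric, mean_a, mean_b, n_a, n_b, sd_a, sd_b, 0.0, df, 1.0
            )
        raise ValueError(
            "degenerate comparison: zero variance in both groups with "
            "unequal means"
        )
    res = stats.ttest_ind(xa, xb, equal_var=not welch)
    df = float(res.df)
    return GroupComparison(
        metric,
        mean_a,
        mean_b,
        n_a,
        n_b,
        sd_a,
        sd_b,
        float(res.statistic),
        df,
        float(res.pvalue),
    )


def group_mean_inactivity(
    values: Sequence[float], exclude_zero: bool = False
) -> tuple[float | None, int]:
    """Mean inactivity of a group, optionally excluding zero-inactivity.

    Returns ``(mean, n)`` where ``n`` is the retained count; ``(None, 0)``
    when nothing is retained.
    """
    vals = [float(v) for v in values]
    if any(not 0.0 <= v <= 1.0 for v in vals):
        raise ValueError("inactivity values must lie in [0, 1]")
    if exclude_zero:
        vals = [v for v in vals if v != 0.0]
    if not vals:
        return None, 0
    return sum(vals) / len(vals), len(vals)


def normalize_to_baseline(tc: TimeCourse) -> TimeCourse:
    """Express a time course as percent of its baseline-stage value.

    The baseline stage must be present with a positive value; after
    normalisation it maps to 100.  Normalising an already-normalised series
    with the same baseline is the identity.
    """
    stages = [s for s, _ in tc.points]
    if any(s1 <= s0 for s0, s1 in zip(stages, stages[1:])):
        raise ValueError("stages must be strictly increasing")
    baseline_value = None
    for s, v in tc.points:
        if s == tc.baseline_stage:
            baseline_value = v
            break
    if baseline_value is None:
        raise ValueError(
            f"baseline stage {tc.baseline_stage:g} not present in the series"
        )
    if baseline_value <= 0:
        raise ValueError("baseline value must be > 0")
    points = tuple((s, 100.0 * v / baseline_value) for s, v in tc.points)
    return TimeCourse(points=points, baseline_stage=tc.baseline_stage)


def fit_poly2(points: Sequence[tuple[float, float]]) -> PolyFit:
    """Ordinary least-squares quadratic through ``(x, y)`` points.

    Requires at least three points with three distinct x values; exact on
    noiseless quadratic data.
    """
    if len(points) < 3 or len({x for x, _ in points}) < 3:
        raise ValueError("need >= 3 points with >= 3 distinct x values")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    c = npoly.polyfit(x, y, 2)
    resid = y - npoly.polyval(x, c)
    return PolyFit(float(c[0]), float(c[1]), float(c[2]), float(resid @ resid))


def poly_eval(fit: PolyFit, x: float) -> float:
    """Evaluate ``c0 + c1*x + c2*x**2``."""
    return fit.c0 + fit.c1 * x + fit.c2 * x * x
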