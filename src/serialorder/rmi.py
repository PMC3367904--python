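"""Race model inequality (RMI) test on derived-list RT distributions.

If position-item and item-item knowledge act as independent parallel
channels, the CDF of fixed-sequence RTs (both cues available) can never
exceed the sum of the single-cue CDFs:

    F_fixed(t) <= F_ordinal(t) + F_order(t)   for all t.

A violation at the fast tail indicates coactivation - the two knowledge
sources pooling into one retrieval process.  Per participant we estimate
each condition's CDF at ten percentile levels (5%, 15%, ..., 95%) by linear
interpolation of the order statistics, estimate the bound's quantile
function from the equal-weight pooled single-cue sample, and compare the
two across participants with paired one-tailed t-tests, Bonferroni-adjusted
over a restricted range of fast percentiles where violations can occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import exclude_trials

__all__ = [
    "DEFAULT_LEVELS",
    "percentile_points",
    "sum_cdf_percentiles",
    "rmi_test",
    "RMIResult",
    "condition_percentiles",
    "race_model_test",
]

#: ten percentile levels, midpoints of deciles
DEFAULT_LEVELS: tuple[float, ...] = tuple(np.round(np.arange(0.05, 1.0, 0.10), 2))

#: fast-tail levels over which violations are assessed (5-20% range)
DEFAULT_RESTRICTED: tuple[float, ...] = (0.05, 0.15)


def percentile_points(
    rts: Sequence[float], levels: Sequence[float] = DEFAULT_LEVELS
) -> np.ndarray:
    """Empirical quantiles at ``levels`` via linear interpolation of order
    statistics at plotting positions (i - 0.5) / n, clamped to the sample
    range outside it."""
    x = np.asarray(rts, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 RTs to estimate percentile points")
    return np.quantile(x, np.asarray(levels, dtype=float), method="hazen")


def _cdf_limits(sample: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous value and left limit of the interpolated empirical
    CDF at points ``t``.

    The CDF is piecewise linear through the plotting positions
    (x_(i), (i - 0.5)/n) and jumps to 0 below the sample minimum and to 1 at
    the maximum, so its generalized inverse is exactly the clamped
    interpolated quantile function."""
    x = np.sort(sample)
    n = x.size
    pos = (np.arange(1, n + 1) - 0.5) / n
    interp = np.interp(t, x, pos)
    right = np.where(t < x[0], 0.0, np.where(t >= x[-1], 1.0, interp))
    left = np.where(t <= x[0], 0.0, np.where(t > x[-1], 1.0, interp))
    return right, left


def sum_cdf_percentiles(
    order_rts: Sequence[float],
    ordinal_rts: Sequence[float],
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> np.ndarray:
    """Quantiles of the race-model bound F_order + F_ordinal.

    The bound's quantile at level p is the generalized inverse, at p/2, of
    the equal-weight mixture G = (F_order + F_ordinal)/2 - each condition
    contributes probability mass 1/2 regardless of its sample size, with
    each CDF estimated by the same interpolation as the single-condition
    percentile points.  By construction the result never exceeds either
    single-condition quantile at the same level.
    """
    x = np.asarray(order_rts, dtype=float)
    y = np.asarray(ordinal_rts, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    bp = np.unique(np.concatenate([x, y]))  # G is linear between these
    xr, xl = _cdf_limits(x, bp)
    yr, yl = _cdf_limits(y, bp)
    g_right = (xr + yr) / 2.0
    g_left = (xl + yl) / 2.0

    out = np.empty(len(levels))
    for i, lvl in enumerate(np.asarray(levels, dtype=float)):
        q = lvl / 2.0
        j = int(np.searchsorted(g_right, q, side="left"))
        if j >= bp.size:
            out[i] = bp[-1]
        elif j == 0 or g_left[j] < q or g_left[j] <= g_right[j - 1]:
            # reached at (or clamped to) a breakpoint / jump
            out[i] = bp[j]
        else:
            # rising linear segment from (bp[j-1], g_right[j-1]) to (bp[j], g_left[j])
            frac = (q - g_right[j - 1]) / (g_left[j] - g_right[j - 1])
            out[i] = bp[j - 1] + frac * (bp[j] - bp[j - 1])
    return out


@dataclass
class RMIResult:
    """Per-level group comparison of the fixed-condition CDF against the
    summed single-cue bound."""

    levels: tuple[float, ...]
    restricted_levels: tuple[float, ...]
    alpha: float
    n_participants: int
    mean_fixed: np.ndarray      # per-level mean RT, fixed condition
    mean_sum: np.ndarray        # per-level mean RT, order+ordinal bound
    t: np.ndarray
    df: int
    p: np.ndarray               # raw one-tailed p (fixed faster than bound)
    p_adjusted: np.ndarray      # Bonferroni over the restricted comparisons
    violation: bool = field(default=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.levels,
                "mean_fixed_ms": self.mean_fixed,
                "mean_bound_ms": self.mean_sum,
                "t": self.t,
                "p": self.p,
                "p_adjusted": self.p_adjusted,
                "restricted": [l in self.restricted_levels for l in self.levels],
            }
        )


def rmi_test(
    fixed_points: np.ndarray,
    sum_points: np.ndarray,
    levels: Sequence[float] = DEFAULT_LEVELS,
    restricted_levels: Sequence[float] = DEFAULT_RESTRICTED,
    alpha: float = 0.05,
) -> RMIResult:
    """Test the race model inequality across participants.

    ``fixed_points`` and ``sum_points`` are participants x levels arrays of
    per-participant percentile points (rows aligned).  At each level a
    paired one-tailed t-test asks whether fixed-condition RTs undercut the
    bound; p-values at the restricted fast-tail levels are Bonferroni
    multiplied by the number of restricted comparisons, and a violation is
    declared iff any restricted adjusted p falls below ``alpha``.
    """
    F = np.asarray(fixed_points, dtype=float)
    S = np.asarray(sum_points, dtype=float)
    if F.shape != S.shape or F.ndim != 2:
        raise ValueError("fixed and sum percentile arrays must share shape (n, levels)")
    n = F.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    levels = tuple(float(l) for l in levels)
    restricted = tuple(float(l) for l in restricted_levels)
    if not set(restricted) <= set(levels):
        raise ValueError("restricted levels must be a subset of the level grid")

    d = F - S
    mean_d = d.mean(axis=0)
    sd_d = d.std(axis=0, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd_d / np.sqrt(n))
        # degenerate zero-variance columns: the sign of the mean decides
        degenerate = np.where(mean_d == 0, 0.0, np.sign(mean_d) * np.inf)
    t = np.where(sd_d == 0, degenerate, t)
    p = sps.t.cdf(t, df)  # one-tailed: evidence that fixed < bound
    p = np.where(np.isneginf(t), 0.0, np.where(np.isposinf(t), 1.0, p))
    factor = max(1, len(restricted))
    p_adj = np.minimum(1.0, p * factor)
    is_restricted = np.array([l in restricted for l in levels])
    violation = bool(np.any(p_adj[is_restricted] < alpha))
    return RMIResult(
        levels=levels,
        restricted_levels=restricted,
        alpha=alpha,
        n_participants=n,
        mean_fixed=F.mean(axis=0),
        mean_sum=S.mean(axis=0),
        t=t,
        df=df,
        p=p,
        p_adjusted=p_adj,
        violation=violation,
    )


def condition_percentiles(
    data: pd.DataFrame,
    levels: Sequence[float] = DEFAULT_LEVELS,
    already_filtered: bool = False,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Per-participant percentile points for the fixed condition and for the
    order+ordinal bound, pooling RTs across sessions.

    Returns (fixed_points, sum_points, participants); rows aligned.
    """
    df = data if already_filtered else exclude_trials(data)
    fixed_rows, sum_rows, participants = [], [], []
    for pt, g in df.groupby("participant", sort=True):
        fixed = g.loc[g["condition"] == "fixed", "rt_ms"].to_numpy()
        order = g.loc[g["tag"] == "order_test", "rt_ms"].to_numpy()
        ordinal = g.loc[g["tag"] == "ordinal_test", "rt_ms"].to_numpy()
        if fixed.size < 2 or order.size == 0 or ordinal.size == 0:
            continue
        fixed_rows.append(percentile_points(fixed, levels))
        sum_rows.append(sum_cdf_percentiles(order, ordinal, levels))
        participants.append(pt)
    if not participants:
        raise ValueError("no participant has all three conditions")
    return np.vstack(fixed_rows), np.vstack(sum_rows), participants


def race_model_test(
    data: pd.DataFrame,
    levels: Sequence[float] = DEFAULT_LEVELS,
    restricted_levels: Sequence[float] = DEFAULT_RESTRICTED,
    alpha: float = 0.05,
) -> RMIResult:
    """End-to-end RMI test on a trial table (exclusion, CDF estimation, test)."""
    F, S, _ = condition_percentiles(data, levels)
    return rmi_test(F, S, levels, restricted_levels, alpha)
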