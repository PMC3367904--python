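"""Within-subject inferential statistics for the difference-score analyses.

The two-way repeated-measures ANOVA uses the classical within-subjects
sums-of-squares decomposition: each effect (factor A, factor B, A x B) is
tested against its own subject-by-effect interaction mean square, with
uncorrected degrees of freedom (no sphericity correction).  Within-subject
error bars follow the interaction-mean-square construction (Loftus-Masson /
Masson), yielding one shared SE across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "rm_anova_2way",
    "RMAnovaResult",
    "linreg_session",
    "RegressionResult",
    "paired_t",
    "correlations",
    "within_subject_se",
    "WithinSubjectSE",
]


@dataclass
class RMAnovaResult:
    """F tests for the two main effects and the interaction."""

    table: pd.DataFrame          # effect, df1, df2, F, p
    cell_means: pd.DataFrame     # A x B table of means

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def _cube(
    data: pd.DataFrame, dv: str, within: Sequence[str], subject: str
) -> tuple[np.ndarray, list, list]:
    wide = data.pivot_table(index=subject, columns=list(within), values=dv)
    if wide.isna().any().any():
        raise ValueError("missing cells: the design must be complete and balanced")
    a_levels = sorted({k[0] for k in wide.columns})
    b_levels = sorted({k[1] for k in wide.columns})
    cube = np.empty((wide.shape[0], len(a_levels), len(b_levels)))
    for i, a in enumerate(a_levels):
        for j, b in enumerate(b_levels):
            cube[:, i, j] = wide[(a, b)].to_numpy()
    return cube, a_levels, b_levels


def rm_anova_2way(
    data: pd.DataFrame,
    dv: str = "median_rt_ms",
    within: Sequence[str] = ("block", "condition"),
    subject: str = "participant",
) -> RMAnovaResult:
    """Two-way fully within-subjects ANOVA on a long-format table.

    Requires one observation per subject x A x B cell (aggregate first).
    Error terms are the subject-by-effect interactions; at least two levels
    per factor.
    """
    Y, a_levels, b_levels = _cube(data, dv, within, subject)
    n, a, b = Y.shape
    if a < 2 or b < 2 or n < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")
    gm = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)
    m_as = Y.mean(axis=2)
    m_bs = Y.mean(axis=1)

    ss_a = n * b * ((m_a - gm) ** 2).sum()
    ss_b = n * a * ((m_b - gm) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_as = b * ((m_as - m_s[:, None] - m_a[None, :] + gm) ** 2).sum()
    ss_bs = a * ((m_bs - m_s[:, None] - m_b[None, :] + gm) ** 2).sum()
    resid = (
        Y
        - m_ab[None, :, :]
        - m_as[:, :, None]
        - m_bs[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - gm
    )
    ss_abs = (resid**2).sum()

    rows = []
    for name, ss_eff, df_eff, ss_err, df_err in (
        (within[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        (within[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        (f"{within[0]}:{within[1]}", ss_ab, (a - 1) * (b - 1), ss_abs,
         (a - 1) * (b - 1) * (n - 1)),
    ):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
        p = float(sps.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
        rows.append((name, df_eff, df_err, F, p))
    table = pd.DataFrame(rows, columns=["effect", "df1", "df2", "F", "p"])
    cell_means = pd.DataFrame(m_ab, index=a_levels, columns=b_levels)
    return RMAnovaResult(table, cell_means)


@dataclass
class RegressionResult:
    slope: float       # standardized coefficient (on z-scored variables)
    t: float
    df: int
    p: float
    r_squared: float
    n: int


def linreg_session(
    scores: pd.DataFrame,
    x: str = "session",
    y: str = "value_ms",
) -> RegressionResult:
    """OLS of a difference score on session index, over all participant-block
    observations, reporting the standardized slope with n - 2 df."""
    xv = scores[x].to_numpy(dtype=float)
    yv = scores[y].to_numpy(dtype=float)
    if np.std(xv) == 0:
        raise ValueError("predictor is constant")
    zx = (xv - xv.mean()) / xv.std(ddof=1)
    zy = (yv - yv.mean()) / yv.std(ddof=1)
    fit = sps.linregress(zx, zy)
    n = len(xv)
    t = float(fit.slope / fit.stderr) if fit.stderr > 0 else np.inf * np.sign(fit.slope)
    return RegressionResult(
        slope=float(fit.slope),
        t=t,
        df=n - 2,
        p=float(fit.pvalue) if np.isfinite(t) else 0.0,
        r_squared=float(fit.rvalue**2),
        n=n,
    )


def paired_t(
    x: Sequence[float],
    y: Sequence[float],
    tail: str = "two-sided",
) -> tuple[float, int, float]:
    """Paired t-test; ``tail`` in {'two-sided', 'less', 'greater'} for the
    alternative mean(x - y) <> 0.  Returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("differences have zero variance")
    res = sps.ttest_rel(x, y, alternative=tail)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def correlations(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
) -> tuple[float, float, float]:
    """Pearson or Spearman correlation with the t-approximation p-value
    (t = r sqrt((n-2)/(1-r^2)) on n - 2 df, as in R's cor.test).
    Returns (r, t, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    if method == "pearson":
        r = float(sps.pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(sps.spearmanr(x, y).statistic)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    n = x.size
    if abs(r) >= 1.0:
        return r, np.inf * np.sign(r), 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = float(2 * sps.t.sf(abs(t), n - 2))
    return r, float(t), p


@dataclass
class WithinSubjectSE:
    """Condition means with one shared within-subject standard error."""

    means: pd.Series
    se: float
    n_participants: int


def within_subject_se(
    data: pd.DataFrame,
    dv: str = "median_rt_ms",
    condition: str = "cell",
    subject: str = "participant",
) -> WithinSubjectSE:
    """Error bars for within-subject designs from the subject-by-condition
    interaction mean square: SE = sqrt(MS_SxC / n), identical across
    conditions."""
    wide = data.pivot_table(index=subject, columns=condition, values=dv)
    if wide.isna().any().any():
        raise ValueError("unbalanced design: every subject needs every condition")
    Y = wide.to_numpy()
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    gm = Y.mean()
    resid = Y - Y.mean(axis=1, keepdims=True) - Y.mean(axis=0, keepdims=True) + gm
    ms_int = (resid**2).sum() / ((n - 1) * (k - 1))
    return WithinSubjectSE(
        means=wide.mean(axis=0), se=float(np.sqrt(ms_int / n)), n_participants=n
    )
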