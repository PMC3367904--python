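"""Explicit-knowledge scoring against a guessing null.

After the final session participants try to reproduce the two fixed
sequences on a response grid (ordered report) and to mark the random-set
and rarely used locations (unordered reports).  Each report is scored as
the probability that a guessing participant would match the truth at least
as well:

* ordered reports - hits are exact position matches; the null distribution
  of hits for a random ordered draw of 4 of the 32 locations is available
  both in closed form (inclusion-exclusion over forced matches) and by
  Monte Carlo;
* unordered reports - hits are set overlaps, scored with the
  hypergeometric upper tail.

A participant whose averaged ordered-report probability falls below 5% is
excluded from RT analyses as possessing explicit knowledge.  The
rare-location score is computed but never used for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .simulate import ExplicitReport

__all__ = [
    "count_ordered_hits",
    "exact_ordered_null",
    "mc_ordered_null",
    "unordered_score",
    "ordered_score",
    "score_participant",
    "KnowledgeScore",
    "EXCLUSION_ALPHA",
]

N_LOCATIONS = 32
LIST_LEN = 4
EXCLUSION_ALPHA = 0.05


def count_ordered_hits(report: Sequence[int], truth: Sequence[int]) -> int:
    """Number of positions where the report names the true location."""
    if len(report) != len(truth):
        raise ValueError("report and truth must have equal length")
    if len(set(report)) != len(report) or len(set(truth)) != len(truth):
        raise ValueError("entries must be distinct within a report")
    return sum(r == t for r, t in zip(report, truth))


def _falling(a: int, b: int) -> int:
    out = 1
    for i in range(b):
        out *= a - i
    return out


def exact_ordered_null(
    n_locations: int = N_LOCATIONS, list_len: int = LIST_LEN
) -> np.ndarray:
    """Exact P(hits = k), k = 0..list_len, for a uniform ordered draw.

    A guess is an ordered draw of ``list_len`` distinct locations out of
    ``n_locations``; a hit is an exact position match with a fixed truth
    list.  Counting draws with exactly k matches: choose the k matched
    positions, then arrange the remaining positions avoiding their own
    truth entries (inclusion-exclusion over the forced matches):

        P(k) = C(L, k) * sum_i (-1)^i C(L-k, i) (n-k-i)_(L-k-i) / (n)_L
    """
    n, L = int(n_locations), int(list_len)
    if not 1 <= L <= n:
        raise ValueError("need 1 <= list_len <= n_locations")
    total = _falling(n, L)
    pmf = np.zeros(L + 1)
    for k in range(L + 1):
        j = L - k
        cnt = sum(
            (-1) ** i * comb(j, i) * _falling(n - k - i, j - i) for i in range(j + 1)
        )
        pmf[k] = comb(L, k) * cnt / total
    assert abs(pmf.sum() - 1.0) < 1e-12
    return pmf


def mc_ordered_null(
    n_locations: int = N_LOCATIONS,
    list_len: int = LIST_LEN,
    reps: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo tail probabilities P(hits >= k), k = 0..list_len.

    Draws ``reps`` uniform ordered guesses and counts position matches
    against a fixed truth (the first ``list_len`` locations; the null is
    invariant to which truth is used).  Deterministic given ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    # first list_len entries of a random permutation: argsort of uniforms
    u = rng.random((reps, n_locations))
    draws = np.argpartition(u, list_len, axis=1)[:, :list_len]
    # argpartition does not order within the partition; order by u
    rows = np.arange(reps)[:, None]
    order = np.argsort(u[rows, draws], axis=1, kind="stable")
    draws = draws[rows, order]
    hits = (draws == np.arange(list_len)).sum(axis=1)
    pmf = np.bincount(hits, minlength=list_len + 1) / reps
    return np.cumsum(pmf[::-1])[::-1]


def ordered_score(
    report: Sequence[int],
    truth: Sequence[int],
    n_locations: int = N_LOCATIONS,
) -> float:
    """Upper-tail probability of at least the observed ordered hits under
    guessing (exact closed form)."""
    k = count_ordered_hits(report, truth)
    pmf = exact_ordered_null(n_locations, len(truth))
    return float(pmf[k:].sum())


def unordered_score(
    n_reported: int,
    hits: int,
    pool: int = N_LOCATIONS,
    truth_size: int = LIST_LEN,
) -> float:
    """Hypergeometric upper tail P(X >= hits) for an unordered report.

    X counts the overlap between ``n_reported`` marked locations and the
    ``truth_size`` true ones out of ``pool``.
    """
    if hits > min(n_reported, truth_size) or hits < 0:
        raise ValueError("inconsistent hit count")
    return float(sps.hypergeom(pool, truth_size, n_reported).sf(hits - 1))


@dataclass
class KnowledgeScore:
    """Guessing-null probabilities for one participant's reports."""

    participant: Optional[int]
    p_fixed: Optional[float]   # mean of the two ordered-report tail probabilities
    p_random: Optional[float]  # unordered tail probability, random-set report
    p_rare: Optional[float]    # unordered tail probability, rare-location report
    excluded: bool             # True iff p_fixed < 5%
    missing_report: bool = False


def score_participant(
    report: Optional[ExplicitReport],
    fixed_truths: Sequence[Sequence[int]],
    random_truth: Sequence[int] = (),
    rare_truth: Sequence[int] = (),
    n_locations: int = N_LOCATIONS,
    participant: Optional[int] = None,
    alpha: float = EXCLUSION_ALPHA,
) -> KnowledgeScore:
    """Score one participant's reports and apply the exclusion rule.

    ``p_fixed`` averages the two ordered-report tail probabilities; the
    participant is excluded iff it falls below ``alpha``.  The rare-location
    score is informational only.  A lost report is flagged, not excluded.
    """
    if report is None:
        return KnowledgeScore(participant, None, None, None, False, True)
    ps = [
        ordered_score(rep, truth, n_locations)
        for rep, truth in zip(report.fixed_reports, fixed_truths)
    ]
    p_fixed = float(np.mean(ps))
    p_random = p_rare = None
    if random_truth:
        hits = len(set(report.random_report) & set(random_truth))
        p_random = unordered_score(
            len(report.random_report), hits, n_locations, len(set(random_truth))
        )
    if rare_truth:
        hits = len(set(report.rare_report) & set(rare_truth))
        p_rare = unordered_score(
            len(report.rare_report), hits, n_locations, len(set(rare_truth))
        )
    return KnowledgeScore(
        participant, p_fixed, p_random, p_rare, excluded=p_fixed < alpha
    )
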