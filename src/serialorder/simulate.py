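"""Generative reaction-time model for the derived-list SRT task.

RTs are drawn from a shifted-lognormal visual-search baseline and speeded by
two learned association sources with separate exponential practice curves:

* a *position-item* source (serial position cues the item), fast to
  asymptote early in training;
* an *item-item* source (the preceding item cues its successor), slower,
  still rising across sessions.

Which sources are available on a trial follows from its derived-list role:
fixed-sequence trials expose both cues, ordinal-only test trials the
position cue alone, order-only test trials the item cue alone, and
random / control / new-location trials none.

Two expression architectures are provided.  Under ``race`` the available
cues race: each contributes an independently perturbed facilitation draw
and the largest one wins, so the combined condition can never beat the
summed single-cue CDF bound (the race model inequality holds by
construction).  Under ``coactivation`` the cues pool: facilitations add,
plus an over-additive interaction bonus when both are present, which
violates the bound at the fast tail.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .design import SEQ_LEN, FIXED_ROLES, GridLocation, SequenceSpec

__all__ = [
    "SimParams",
    "learning_curve",
    "trial_rt",
    "simulate_participant",
    "simulate_cohort",
    "simulate_reports",
    "ExplicitReport",
    "compile_design",
    "CompiledDesign",
]

RT_FLOOR_MS = 100.0


@dataclass
class SimParams:
    """Parameters of the generative RT model.

    Units are milliseconds throughout; learning-curve rates are per
    exposure (one completed mini-block of the relevant fixed sequence).
    """

    baseline_shift: float = 300.0  # irreducible motor/encoding time
    baseline_mu: float = 6.2       # log-scale location, exp(mu) ~ 493 ms
    baseline_sigma: float = 0.35   # log-scale dispersion
    s_pos_asym: float = 90.0       # position-item facilitation asymptote
    s_pos_rate: float = 0.03       # fast: ~97% of asymptote after one session
    s_item_asym: float = 70.0      # item-item facilitation asymptote
    s_item_rate: float = 0.004     # slow: still rising in session 3
    architecture: str = "race"     # race | coactivation
    race_channel_sigma: float = 30.0   # per-channel retrieval-time noise
    coactivation_bonus: float = 80.0   # over-additive gain when both cues pool
    error_rate: float = 0.03
    n_participants: int = 21
    between_subject_sd: float = 0.2    # lognormal sd on asymptote multipliers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("race", "coactivation"):
            raise ValueError("architecture must be 'race' or 'coactivation'")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        for name in ("s_pos_asym", "s_pos_rate", "s_item_asym", "s_item_rate",
                     "race_channel_sigma", "coactivation_bonus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def learning_curve(n, asym: float, rate: float):
    """Exponential practice curve: facilitation after ``n`` exposures.

    ``asym * (1 - exp(-rate * n))``; 0 at n = 0, saturating at ``asym``.
    Accepts scalar or array ``n``.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0) or asym < 0 or rate < 0:
        raise ValueError("learning_curve arguments must be non-negative")
    out = asym * (1.0 - np.exp(-rate * n))
    return float(out) if out.ndim == 0 else out


def _facilitation(
    has_pos: np.ndarray,
    has_item: np.ndarray,
    s_pos: np.ndarray,
    s_item: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-trial facilitation (ms) under the chosen architecture, vectorized."""
    if params.architecture == "race":
        draw_pos = np.where(
            has_pos,
            np.maximum(0.0, s_pos + rng.normal(0.0, params.race_channel_sigma, s_pos.shape)),
            -np.inf,
        )
        draw_item = np.where(
            has_item,
            np.maximum(0.0, s_item + rng.normal(0.0, params.race_channel_sigma, s_item.shape)),
            -np.inf,
        )
        facil = np.maximum(draw_pos, draw_item)
        return np.where(np.isfinite(facil), facil, 0.0)
    facil = np.where(has_pos, s_pos, 0.0) + np.where(has_item, s_item, 0.0)
    facil = facil + np.where(has_pos & has_item, params.coactivation_bonus, 0.0)
    return facil


def trial_rt(
    cues: Iterable[str],
    s_pos: float,
    s_item: float,
    params: SimParams,
    rng: np.random.Generator,
) -> float:
    """Draw one RT given the available cues ('position' and/or 'item')."""
    cues = set(cues)
    unknown = cues - {"position", "item"}
    if unknown:
        raise ValueError(f"unknown cues: {sorted(unknown)}")
    baseline = params.baseline_shift + rng.lognormal(params.baseline_mu, params.baseline_sigma)
    facil = _facilitation(
        np.array(["position" in cues]),
        np.array(["item" in cues]),
        np.array([float(s_pos)]),
        np.array([float(s_item)]),
        params,
        rng,
    )[0]
    return float(max(RT_FLOOR_MS, baseline - facil))


# ---------------------------------------------------------------------------
# vectorized whole-table simulation
# ---------------------------------------------------------------------------

@dataclass
class CompiledDesign:
    """Static per-trial arrays extracted once from a design table."""

    n_trials: int
    has_pos: np.ndarray   # bool: position-item cue available
    has_item: np.ndarray  # bool: item-item cue available
    n_exposures: np.ndarray  # float: completed mini-blocks of the cue's sequence
    session: np.ndarray   # int session index per trial
    block: np.ndarray     # int block index per trial
    is_fixed: np.ndarray
    is_ordinal_test: np.ndarray
    is_order_test: np.ndarray
    is_new_location: np.ndarray


def compile_design(design: pd.DataFrame) -> CompiledDesign:
    """Precompute cue availability and exposure counts for every trial.

    Exposure counters advance once per completed fixed-condition mini-block
    of each fixed sequence; ordinal/order test trials read the counter of the
    sequence their test item belongs to.
    """
    df = design.sort_values(
        ["session", "block", "mini_block", "serial_position"], kind="stable"
    )
    cond = df["condition"].to_numpy()
    tag = df["tag"].to_numpy()
    role = df["sequence_role"].to_numpy()
    has_pos = (cond == "fixed") | (tag == "ordinal_test")
    has_item = (cond == "fixed") | (tag == "order_test")

    # mini-block index per trial; exposures = fixed mini-blocks of same role
    # completed strictly before the current mini-block
    mb_first = df["serial_position"].to_numpy() == 1
    n_exp = np.zeros(len(df))
    counters = {r: 0 for r in FIXED_ROLES}
    counts_by_role = {r: np.zeros(len(df)) for r in FIXED_ROLES}
    # vectorizable, but the single pass over mini-blocks is cheap and clear
    current = dict(counters)
    for i in range(len(df)):
        if mb_first[i]:
            if i > 0 and cond[i - 1] == "fixed":
                current[role[i - 1]] += 1
            for r in FIXED_ROLES:
                counts_by_role[r][i] = current[r]
        else:
            for r in FIXED_ROLES:
                counts_by_role[r][i] = counts_by_role[r][i - 1]
    for r in FIXED_ROLES:
        n_exp = np.where(role == r, counts_by_role[r], n_exp)
    return CompiledDesign(
        len(df), has_pos, has_item, n_exp,
        session=df["session"].to_numpy(),
        block=df["block"].to_numpy(),
        is_fixed=cond == "fixed",
        is_ordinal_test=tag == "ordinal_test",
        is_order_test=tag == "order_test",
        is_new_location=tag == "new_location",
    )


def _simulate_arrays(
    compiled: CompiledDesign,
    params: SimParams,
    rng: np.random.Generator,
    asym_mult_pos: float = 1.0,
    asym_mult_item: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (rt_ms, correct) arrays for one participant."""
    n = compiled.n_trials
    s_pos = learning_curve(compiled.n_exposures, params.s_pos_asym * asym_mult_pos,
                           params.s_pos_rate)
    s_item = learning_curve(compiled.n_exposures, params.s_item_asym * asym_mult_item,
                            params.s_item_rate)
    baseline = params.baseline_shift + rng.lognormal(
        params.baseline_mu, params.baseline_sigma, n
    )
    facil = _facilitation(compiled.has_pos, compiled.has_item, s_pos, s_item, params, rng)
    correct = rng.random(n) >= params.error_rate
    # errors reflect a failed search: no learned facilitation applies
    rt = np.where(correct, baseline - facil, baseline)
    return np.maximum(RT_FLOOR_MS, rt), correct


def simulate_participant(
    design: pd.DataFrame,
    params: SimParams,
    participant_seed: int,
) -> pd.DataFrame:
    """Fill rt_ms and correct for one participant's design table.

    Deterministic given ``participant_seed``.  Between-subject heterogeneity
    (lognormal multipliers on the two asymptotes) is drawn from the same
    seed stream.
    """
    rng = np.random.default_rng(int(participant_seed) & 0x7FFFFFFF)
    m_pos, m_item = np.exp(rng.normal(0.0, params.between_subject_sd, 2))
    compiled = compile_design(design)
    rt, correct = _simulate_arrays(compiled, params, rng, m_pos, m_item)
    out = design.sort_values(
        ["session", "block", "mini_block", "serial_position"], kind="stable"
    ).copy()
    out["rt_ms"] = rt
    out["correct"] = correct
    return out


def simulate_cohort(
    design: pd.DataFrame,
    params: SimParams,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate ``params.n_participants`` participants on the same design.

    Participant ids are 1..n; each participant gets an independent seed
    derived from ``seed`` (default ``params.seed``).
    """
    base = params.seed if seed is None else seed
    frames = []
    for p in range(1, params.n_participants + 1):
        pseed = int(np.random.default_rng([int(base) & 0x7FFFFFFF, p]).integers(2**31))
        df = simulate_participant(design, params, pseed)
        df["participant"] = p
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# explicit-report simulation
# ---------------------------------------------------------------------------

@dataclass
class ExplicitReport:
    """A participant's post-experiment verbal report.

    ``fixed_reports`` are the two ordered four-location recalls of the fixed
    sequences; ``random_report`` and ``rare_report`` are unordered location
    sets for the random-set and rarely-seen locations.
    """

    fixed_reports: tuple[tuple[int, ...], tuple[int, ...]]
    random_report: frozenset
    rare_report: frozenset

    def __post_init__(self) -> None:
        for rep in self.fixed_reports:
            if len(set(rep)) != len(rep):
                raise ValueError("report entries must be distinct")


def _noisy_ordered_report(
    truth: Sequence[int], k: float, pool: Sequence[int], rng: np.random.Generator
) -> tuple[int, ...]:
    report: list[int] = []
    for pos, true_cell in enumerate(truth):
        if true_cell not in report and rng.random() < k:
            report.append(true_cell)
        else:
            remaining = [c for c in pool if c not in report]
            report.append(int(remaining[int(rng.integers(len(remaining)))]))
    return tuple(report)


def _noisy_set_report(
    truth: Sequence[int], size: int, k: float, pool: Sequence[int],
    rng: np.random.Generator,
) -> frozenset:
    report: list[int] = []
    truth = list(truth)
    for _ in range(size):
        candidates_true = [c for c in truth if c not in report]
        if candidates_true and rng.random() < k:
            report.append(candidates_true[int(rng.integers(len(candidates_true)))])
        else:
            remaining = [c for c in pool if c not in report]
            report.append(int(remaining[int(rng.integers(len(remaining)))]))
    return frozenset(report)


def simulate_reports(
    truths: dict[str, SequenceSpec],
    knowledge: float,
    rng: np.random.Generator,
    reserved: Optional[Sequence[GridLocation]] = None,
    n_locations: int = 32,
    random_report_size: int = 8,
    rare_report_size: int = 4,
) -> ExplicitReport:
    """Generate a verbal report with graded knowledge ``k`` in [0, 1].

    Each reported entry matches the truth with probability ``k`` and is
    otherwise drawn uniformly from the not-yet-reported locations, so k = 1
    reproduces the truth and k = 0 is pure guessing.
    """
    if not 0 <= knowledge <= 1:
        raise ValueError("knowledge must be in [0, 1]")
    pool = list(range(n_locations))
    fixed_reports = tuple(
        _noisy_ordered_report(
            [loc.cell_index for loc in truths[role].items], knowledge, pool, rng
        )
        for role in FIXED_ROLES
    )
    random_truth = [
        loc.cell_index for role in ("random_setA", "random_setB")
        if role in truths for loc in truths[role].items
    ]
    random_report = _noisy_set_report(
        random_truth, random_report_size, knowledge, pool, rng
    )
    rare_truth = [loc.cell_index for loc in (reserved or [])]
    rare_report = _noisy_set_report(
        rare_truth, rare_report_size, knowledge, pool, rng
    )
    return ExplicitReport(fixed_reports, random_report, rare_report)  # type: ignore[arg-type]
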