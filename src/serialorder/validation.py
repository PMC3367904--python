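"""Simulation studies validating the analysis pipeline on synthetic cohorts.

These run the full generative model + analysis chain many times to check
that (a) the race-model-inequality test controls its type-I rate when the
two knowledge sources really do race independently, and has power to detect
a coactivated architecture; (b) the difference-score pipeline recovers the
qualitative time-course dissociation (early, stable position-item advantage
vs. a slowly rising item-item advantage); (c) least squares on the
block-wise advantage trajectories recovers the generating learning curves.

All cohorts share one design table: counterbalancing rotates locations
across participants, a spatial factor the RT model does not represent, so
regenerating the design per participant would only add cost.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .design import DesignSpec, make_experiment
from .rmi import DEFAULT_LEVELS, DEFAULT_RESTRICTED, percentile_points, rmi_test, sum_cdf_percentiles
from .simulate import CompiledDesign, SimParams, compile_design, _simulate_arrays

__all__ = [
    "default_design",
    "rmi_validation_study",
    "trajectory_study",
    "advantage_trajectory",
    "fit_learning_curve",
]


def default_design(seed: int = 0, participant: int = 1) -> pd.DataFrame:
    """The standard three-session design table for one participant."""
    return make_experiment(DesignSpec(seed=seed, participant=participant))


def _exclusion_mask(compiled: CompiledDesign, correct: np.ndarray) -> np.ndarray:
    """Keep correct trials not immediately preceded by an error in-session."""
    prev_error = np.empty_like(correct)
    prev_error[0] = False
    prev_error[1:] = ~correct[:-1]
    same_session = np.empty(compiled.n_trials, dtype=bool)
    same_session[0] = False
    same_session[1:] = compiled.session[1:] == compiled.session[:-1]
    return correct & ~(prev_error & same_session)


def _cohort_rts(
    compiled: CompiledDesign,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(rt, keep) arrays of shape (n_participants, n_trials)."""
    n = params.n_participants
    rt = np.empty((n, compiled.n_trials))
    keep = np.empty((n, compiled.n_trials), dtype=bool)
    for p in range(n):
        m_pos, m_item = np.exp(rng.normal(0.0, params.between_subject_sd, 2))
        r, c = _simulate_arrays(compiled, params, rng, m_pos, m_item)
        rt[p] = r
        keep[p] = _exclusion_mask(compiled, c)
    return rt, keep


def rmi_validation_study(
    architecture: str,
    n_cohorts: int = 500,
    params: Optional[SimParams] = None,
    seed: int = 0,
    design: Optional[pd.DataFrame] = None,
    alpha: float = 0.05,
) -> dict:
    """Violation rate of the RMI test over simulated cohorts.

    Under ``race`` the inequality holds by construction, so the rate bounds
    the test's type-I error; under ``coactivation`` the rate is its power.
    Returns a dict with the violation rate and study sizes.
    """
    params = replace(params or SimParams(), architecture=architecture)
    compiled = compile_design(design if design is not None else default_design(seed))
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 11])
    levels = np.asarray(DEFAULT_LEVELS)
    violations = 0
    for _ in range(n_cohorts):
        rt, keep = _cohort_rts(compiled, params, rng)
        F_rows, S_rows = [], []
        for p in range(params.n_participants):
            k = keep[p]
            fixed = rt[p][compiled.is_fixed & k]
            order = rt[p][compiled.is_order_test & k]
            ordinal = rt[p][compiled.is_ordinal_test & k]
            F_rows.append(percentile_points(fixed, levels))
            S_rows.append(sum_cdf_percentiles(order, ordinal, levels))
        res = rmi_test(np.vstack(F_rows), np.vstack(S_rows),
                       levels, DEFAULT_RESTRICTED, alpha)
        violations += res.violation
    return {
        "architecture": architecture,
        "violation_rate": violations / n_cohorts,
        "n_cohorts": n_cohorts,
        "n_participants": params.n_participants,
        "alpha": alpha,
    }


def trajectory_study(
    n_cohorts: int = 100,
    params: Optional[SimParams] = None,
    seed: int = 0,
    design: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Session-wise cohort-mean transfer advantages over simulated cohorts.

    For each cohort and session, the ordinal-only and order-only advantages
    (new-location median minus test-trial median, averaged over
    participants).  Used for sign tests of the time-course dissociation.
    """
    params = params or SimParams()
    compiled = compile_design(design if design is not None else default_design(seed))
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 13])
    sessions = np.unique(compiled.session)
    masks = {
        "ordinal": {s: compiled.is_ordinal_test & (compiled.session == s) for s in sessions},
        "order": {s: compiled.is_order_test & (compiled.session == s) for s in sessions},
        "new": {s: compiled.is_new_location & (compiled.session == s) for s in sessions},
    }
    rows = []
    for c in range(n_cohorts):
        rt, keep = _cohort_rts(compiled, params, rng)
        for s in sessions:
            adv_ord, adv_ooo = [], []
            for p in range(params.n_participants):
                k = keep[p]
                new = rt[p][masks["new"][s] & k]
                ordi = rt[p][masks["ordinal"][s] & k]
                oo = rt[p][masks["order"][s] & k]
                if new.size and ordi.size and oo.size:
                    m_new = np.median(new)
                    adv_ord.append(m_new - np.median(ordi))
                    adv_ooo.append(m_new - np.median(oo))
            rows.append(
                (c, int(s), float(np.mean(adv_ord)), float(np.mean(adv_ooo)))
            )
    return pd.DataFrame(
        rows, columns=["cohort", "session", "ordinal_advantage_ms", "order_advantage_ms"]
    )


def advantage_trajectory(
    params: Optional[SimParams] = None,
    seed: int = 0,
    design: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Cohort-mean transfer advantages per transfer block, with the exposure
    count (completed fixed-sequence mini-blocks) at each block."""
    params = params or SimParams()
    compiled = compile_design(design if design is not None else default_design(seed))
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 17])
    rt, keep = _cohort_rts(compiled, params, rng)
    blocks = sorted(
        set(zip(compiled.session[compiled.is_ordinal_test],
                compiled.block[compiled.is_ordinal_test]))
    )
    rows = []
    for i, (s, b) in enumerate(blocks):
        in_block = (compiled.session == s) & (compiled.block == b)
        exposures = float(np.median(compiled.n_exposures[in_block & compiled.is_ordinal_test]))
        adv_ord, adv_ooo = [], []
        for p in range(params.n_participants):
            k = keep[p] & in_block
            new = rt[p][compiled.is_new_location & k]
            ordi = rt[p][compiled.is_ordinal_test & k]
            oo = rt[p][compiled.is_order_test & k]
            if new.size and ordi.size and oo.size:
                m_new = np.median(new)
                adv_ord.append(m_new - np.median(ordi))
                adv_ooo.append(m_new - np.median(oo))
        rows.append((i + 1, int(s), int(b), exposures,
                     float(np.mean(adv_ord)), float(np.mean(adv_ooo))))
    return pd.DataFrame(
        rows,
        columns=["transfer_index", "session", "block", "exposures",
                 "ordinal_advantage_ms", "order_advantage_ms"],
    )


def fit_learning_curve(
    exposures: np.ndarray, advantages: np.ndarray
) -> tuple[float, float]:
    """Least-squares fit of asym * (1 - exp(-rate * n)) to an advantage
    trajectory; returns (asym, rate)."""
    exposures = np.asarray(exposures, dtype=float)
    advantages = np.asarray(advantages, dtype=float)

    def curve(n, asym, rate):
        return asym * (1.0 - np.exp(-rate * n))

    a0 = max(1.0, advantages.max())
    popt, _ = optimize.curve_fit(
        curve, exposures, advantages, p0=(a0, 0.01),
        bounds=((0.0, 1e-6), (np.inf, 1.0)), maxfev=10_000,
    )
    return float(popt[0]), float(popt[1])
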