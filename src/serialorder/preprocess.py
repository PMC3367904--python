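"""Trial exclusion, per-cell medians, and condition difference scores.

Analyses operate on participant-wise cell medians (robust to the heavy right
tail of search RTs).  Error trials and the trial immediately following an
error are excluded (post-error slowing would otherwise contaminate the
condition contrasts); exclusion runs within a session, across mini-block
boundaries.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "exclude_trials",
    "analysis_cells",
    "cell_medians",
    "transfer_contrasts",
    "fixed_vs_random_scores",
    "difference_scores",
]

#: analysis cell per trial: training conditions by condition name, transfer
#: trials by their derived-list tag
_TRANSFER_CELLS = ("ordinal_test", "order_test", "control_test", "new_location")

#: contrast name -> (test cell, reference cell, sign convention)
#: *_vs_new   = new_location - test  (positive = facilitation vs baseline)
#: *_vs_fixed = test - fixed         (positive = cost vs intact sequence)
CONTRASTS = {
    "ordinal_vs_new": ("ordinal_test", "new_location"),
    "order_vs_new": ("order_test", "new_location"),
    "control_vs_new": ("control_test", "new_location"),
    "ordinal_vs_fixed": ("ordinal_test", "fixed"),
    "order_vs_fixed": ("order_test", "fixed"),
    "control_vs_fixed": ("control_test", "fixed"),
}


def exclude_trials(data: pd.DataFrame) -> pd.DataFrame:
    """Drop error trials and the immediately following trial.

    The follower is dropped within the same participant and session only
    (sessions are separated by days); mini-block boundaries do not protect a
    trial from post-error exclusion.  Idempotent.
    """
    if "correct" not in data.columns:
        raise ValueError("data must carry a 'correct' column")
    df = data.sort_values(
        ["participant", "session", "block", "mini_block", "serial_position"],
        kind="stable",
    )
    is_error = ~df["correct"].astype(bool)
    post_error = (
        is_error.groupby([df["participant"], df["session"]]).shift(1, fill_value=False)
    )
    return df[~is_error & ~post_error]


def analysis_cells(data: pd.DataFrame) -> pd.DataFrame:
    """Attach the analysis ``cell`` label and drop unanalyzed trials.

    Training trials keep their condition (fixed / random); transfer trials
    are labelled by their derived-list tag; random-transfer and untagged
    transfer trials are dropped.
    """
    df = data.copy()
    cell = pd.Series("", index=df.index, dtype=object)
    cell[df["condition"] == "fixed"] = "fixed"
    cell[df["condition"] == "random"] = "random"
    transfer = df["tag"].isin(_TRANSFER_CELLS)
    cell[transfer] = df.loc[transfer, "tag"]
    df["cell"] = cell
    return df[df["cell"] != ""]


def cell_medians(
    data: pd.DataFrame, grouping: Sequence[str] = ("session", "block", "cell")
) -> pd.DataFrame:
    """Participant-wise median RT per cell.

    Even-sized cells use the midpoint of the two central order statistics.
    Cells are defined by ``participant`` plus ``grouping`` columns; the trial
    count per cell is recorded alongside.
    """
    keys = ["participant", *grouping]
    g = data.groupby(keys, sort=True)["rt_ms"]
    out = g.median().rename("median_rt_ms").reset_index()
    out["n_trials"] = g.count().to_numpy()
    return out


def fixed_vs_random_scores(medians: pd.DataFrame) -> pd.DataFrame:
    """Per participant and training block: median(random) - median(fixed).

    Positive values mean fixed-sequence trials are faster.
    """
    wide = medians.pivot_table(
        index=["participant", "session", "block"], columns="cell",
        values="median_rt_ms",
    )
    if "fixed" not in wide.columns or "random" not in wide.columns:
        raise ValueError("medians must contain fixed and random cells")
    wide = wide.dropna(subset=["fixed", "random"])
    out = wide.reset_index()[["participant", "session", "block"]].copy()
    out["contrast"] = "fixed_vs_random"
    out["value_ms"] = (wide["random"] - wide["fixed"]).to_numpy()
    return out


def transfer_contrasts(medians: pd.DataFrame) -> pd.DataFrame:
    """All transfer difference scores, per participant and transfer block.

    The fixed-sequence reference for the ``*_vs_fixed`` contrasts is the
    fixed-condition median of the immediately preceding training block;
    a missing reference raises.
    """
    wide = medians.pivot_table(
        index=["participant", "session", "block"], columns="cell",
        values="median_rt_ms",
    )
    fixed_ref = wide.get("fixed")
    rows = []
    transfer = wide[wide.reindex(columns=list(_TRANSFER_CELLS)).notna().any(axis=1)]
    for (pt, sess, blk), row in transfer.iterrows():
        ref_key = (pt, sess, blk - 1)
        if fixed_ref is None or ref_key not in fixed_ref.index or np.isnan(fixed_ref[ref_key]):
            raise ValueError(
                f"no fixed-sequence reference block for participant {pt}, "
                f"session {sess}, transfer block {blk}"
            )
        ref_fixed = fixed_ref[ref_key]
        for name, (test, reference) in CONTRASTS.items():
            test_val = row.get(test, np.nan)
            if np.isnan(test_val):
                continue
            if reference == "fixed":
                value = test_val - ref_fixed
            else:
                ref_val = row.get(reference, np.nan)
                if np.isnan(ref_val):
                    continue
                value = ref_val - test_val
            rows.append((pt, sess, blk, name, value))
    return pd.DataFrame(
        rows, columns=["participant", "session", "block", "contrast", "value_ms"]
    )


def difference_scores(data: pd.DataFrame) -> pd.DataFrame:
    """Full pipeline: exclusion, cell medians, and all difference scores."""
    cells = analysis_cells(exclude_trials(data))
    med = cell_medians(cells)
    return pd.concat(
        [fixed_vs_random_scores(med), transfer_contrasts(med)], ignore_index=True
    )
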