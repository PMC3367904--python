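"""Trial-structure generation for the derived-list serial reaction time task.

The experiment presents visual-search targets at locations on a 6 x 6 grid
with the four corners removed (32 usable cells).  Trials come in mini-blocks
of four, each mini-block carrying one four-element location sequence.  During
training, two fixed sequences repeat verbatim while two random sets of four
locations appear in fresh random orders, so the fixed sequences carry both
deterministic item-item transitions and deterministic position-item
contingencies.  Transfer blocks probe the two knowledge sources separately
with derived lists:

* ordinal-only mini-blocks place one trained item at its learned serial
  position among never-trained locations (position-item cue only);
* order-only mini-blocks preserve exactly one learned transition but put its
  second member at a wrong serial position (item-item cue only), and yield
  control trials (trained item, wrong position, non-predecessor before it)
  as a by-product;
* random-transfer mini-blocks re-use the random sets.

All generation is deterministic given a :class:`DesignSpec` (seed +
participant number); counterbalancing rotates the eight location quadruples
through the eight role slots across an 8-participant cycle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridLocation",
    "SequenceSpec",
    "MiniBlock",
    "DesignSpec",
    "make_grid",
    "is_adjacent",
    "assign_location_sets",
    "make_fixed_sequence",
    "make_training_block",
    "make_ordinal_only_miniblock",
    "make_order_only_miniblock",
    "make_transfer_block",
    "assign_response_sides",
    "make_experiment",
    "classify_transfer_trials",
]

GRID_SIZE = 6
N_LOCATIONS = 32
SEQ_LEN = 4

FIXED_ROLES = ("fixed1", "fixed2")
RANDOM_ROLES = ("random_setA", "random_setB")
ALL_ROLES = FIXED_ROLES + RANDOM_ROLES

#: number of role slots in the counterbalancing rotation: 4 playing roles
#: plus 4 reserved quadruples (16 never-trained locations)
N_SLOTS = 8

_RETRY_CAP = 10_000


class GridLocation(NamedTuple):
    """One usable cell of the 6 x 6 search grid (corners removed)."""

    cell_index: int
    row: int
    col: int


@dataclass(frozen=True)
class SequenceSpec:
    """A role (fixed sequence or random set) and its four locations.

    For fixed roles ``items`` is the learned order; for random sets the
    order is immaterial (each mini-block draws a fresh order).
    """

    role: str
    items: tuple[GridLocation, ...]

    def __post_init__(self) -> None:
        if len(self.items) != SEQ_LEN or len(set(self.items)) != SEQ_LEN:
            raise ValueError(f"{self.role}: need {SEQ_LEN} distinct items")


@dataclass
class MiniBlock:
    """Four consecutive trials carrying one sequence."""

    condition: str  # fixed | random | ordinal_only | order_only | random_transfer
    locations: tuple[GridLocation, ...]
    tags: tuple[str, ...]  # per-trial analysis tag
    sequence_role: Optional[str] = None  # which fixed sequence / random set it draws on

    def __post_init__(self) -> None:
        if len(self.locations) != SEQ_LEN:
            raise ValueError("a mini-block holds exactly 4 trials")
        if len(self.tags) != SEQ_LEN:
            raise ValueError("need one tag per trial")


@dataclass
class DesignSpec:
    """Full parameterization of the three-session experiment."""

    n_sessions: int = 3
    blocks_per_session: int = 18
    miniblocks_per_block: int = 24
    transfer_block_positions: tuple[int, ...] = (6, 12, 18)
    fixed_miniblocks_per_training_block: int = 16  # 8 per fixed sequence
    random_miniblocks_per_training_block: int = 8  # 4 per set
    transfer_composition: dict = field(
        default_factory=lambda: {"ordinal_only": 8, "order_only": 8, "random_transfer": 8}
    )
    max_same_condition_run: int = 3
    rsi_ms: int = 400
    fixation_ms: int = 1000
    seed: int = 0
    participant: int = 1

    def validate(self) -> None:
        n_transfer = len(self.transfer_block_positions)
        if n_transfer and len(set(np.diff(sorted(self.transfer_block_positions)))) > 1:
            raise ValueError("transfer blocks must be evenly spaced")
        total = (
            self.fixed_miniblocks_per_training_block
            + self.random_miniblocks_per_training_block
        )
        if total != self.miniblocks_per_block:
            raise ValueError("training mini-block counts must fill the block")
        if sum(self.transfer_composition.values()) != self.miniblocks_per_block:
            raise ValueError("transfer composition must fill the block")


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

def make_grid() -> list[GridLocation]:
    """Return the 32 usable cells of the 6 x 6 grid, row-major, corners absent."""
    cells: list[GridLocation] = []
    idx = 0
    last = GRID_SIZE - 1
    for row in range(GRID_SIZE):
        for col in range(GRID_SIZE):
            if (row in (0, last)) and (col in (0, last)):
                continue
            cells.append(GridLocation(idx, row, col))
            idx += 1
    assert len(cells) == N_LOCATIONS
    return cells


def is_adjacent(a: GridLocation, b: GridLocation) -> bool:
    """True iff two distinct cells touch (8-neighborhood: orthogonal or diagonal)."""
    if (a.row, a.col) == (b.row, b.col):
        raise ValueError("adjacency is undefined for identical locations")
    return abs(a.row - b.row) <= 1 and abs(a.col - b.col) <= 1


def _no_adjacent_pairs(seq: Sequence[GridLocation]) -> bool:
    return all(not is_adjacent(x, y) for x, y in zip(seq, seq[1:]))


def _valid_orderings(items: Sequence[GridLocation]) -> list[tuple[GridLocation, ...]]:
    return [p for p in itertools.permutations(items) if _no_adjacent_pairs(p)]


# ---------------------------------------------------------------------------
# location sets and fixed sequences
# ---------------------------------------------------------------------------

def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng([int(k) & 0x7FFFFFFF for k in keys])


def assign_location_sets(
    spec: DesignSpec,
) -> tuple[dict[str, SequenceSpec], list[GridLocation]]:
    """Partition the 32 locations into four playing roles and a reserved pool.

    The cohort seed fixes a partition of the grid into eight quadruples; the
    participant number rotates the quadruples through the eight role slots
    (fixed1, fixed2, random_setA, random_setB, 4 x reserved), so that over an
    8-participant cycle every location serves every role exactly once.  Every
    quadruple is vetted to admit at least one ordering with no grid-adjacent
    consecutive pair, so any rotation yields valid fixed sequences.
    """
    grid = make_grid()
    rng = _rng(spec.seed, 101)
    for _ in range(_RETRY_CAP):
        order = rng.permutation(N_LOCATIONS)
        groups = [tuple(grid[i] for i in order[g * 4 : g * 4 + 4]) for g in range(N_SLOTS)]
        if all(_valid_orderings(g) for g in groups):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not partition grid into orderable quadruples")

    offset = (spec.participant - 1) % N_SLOTS
    roles: dict[str, SequenceSpec] = {}
    reserved: list[GridLocation] = []
    for slot in range(N_SLOTS):
        group = groups[(slot + offset) % N_SLOTS]
        if slot < len(ALL_ROLES):
            role = ALL_ROLES[slot]
            if role in FIXED_ROLES:
                roles[role] = make_fixed_sequence(group, spec.seed, role=role)
            else:
                roles[role] = SequenceSpec(role, group)
        else:
            reserved.extend(group)
    return roles, reserved


def make_fixed_sequence(
    items: Sequence[GridLocation], seed: int, role: str = "fixed1"
) -> SequenceSpec:
    """Order four locations so that no consecutive pair is grid-adjacent.

    Deterministic given ``seed``; raises if every one of the 24 orderings
    contains an adjacent pair (e.g. four cells forming a 2 x 2 square).
    """
    if len(items) != SEQ_LEN or len(set(items)) != SEQ_LEN:
        raise ValueError("need 4 distinct locations")
    valid = _valid_orderings(items)
    if not valid:
        cells = [loc.cell_index for loc in items]
        raise ValueError(f"no non-adjacent ordering exists for item set {cells}")
    rng = _rng(seed, 211, *(loc.cell_index for loc in items))
    return SequenceSpec(role, valid[int(rng.integers(len(valid)))])


# ---------------------------------------------------------------------------
# mini-block construction
# ---------------------------------------------------------------------------

def _random_order_miniblock(
    seq: SequenceSpec, condition: str, rng: np.random.Generator
) -> MiniBlock:
    """A random-set mini-block: fresh draw without replacement, no adjacent pair."""
    valid = _valid_orderings(seq.items)
    order = valid[int(rng.integers(len(valid)))]
    return MiniBlock(condition, order, ("plain",) * SEQ_LEN, sequence_role=seq.role)


def _interleave(labels: list[str], max_run: int, rng: np.random.Generator,
                collapse: Optional[dict] = None) -> list[int]:
    """Return a permutation of ``range(len(labels))`` whose label sequence has
    no run longer than ``max_run``.  ``collapse`` maps labels to coarser
    condition classes before run counting.  Rejection sampling, bounded."""
    coarse = [collapse.get(l, l) if collapse else l for l in labels]
    idx = np.arange(len(labels))
    for _ in range(_RETRY_CAP):
        perm = rng.permutation(idx)
        run, longest, prev = 0, 0, None
        for i in perm:
            c = coarse[i]
            run = run + 1 if c == prev else 1
            prev = c
            longest = max(longest, run)
        if longest <= max_run:
            return [int(i) for i in perm]
    raise RuntimeError("could not interleave mini-blocks under the run-length constraint")


def make_training_block(
    spec: DesignSpec, sequences: dict[str, SequenceSpec], seed: int
) -> list[MiniBlock]:
    """One training block: 8+8 fixed-sequence and 4+4 random-set mini-blocks,
    pseudo-randomly interleaved with no more than ``max_same_condition_run``
    consecutive mini-blocks of the same condition (fixed vs random)."""
    rng = _rng(seed, 307)
    pool: list[MiniBlock] = []
    labels: list[str] = []
    n_fix = spec.fixed_miniblocks_per_training_block // len(FIXED_ROLES)
    n_rand = spec.random_miniblocks_per_training_block // len(RANDOM_ROLES)
    for role in FIXED_ROLES:
        seq = sequences[role]
        for _ in range(n_fix):
            pool.append(MiniBlock("fixed", seq.items, ("plain",) * SEQ_LEN, role))
            labels.append(role)
    for role in RANDOM_ROLES:
        for _ in range(n_rand):
            pool.append(_random_order_miniblock(sequences[role], "random", rng))
            labels.append(role)
    collapse = {r: "fixed" for r in FIXED_ROLES}
    collapse.update({r: "random" for r in RANDOM_ROLES})
    order = _interleave(labels, spec.max_same_condition_run, rng, collapse)
    return [pool[i] for i in order]


def make_ordinal_only_miniblock(
    fixed: SequenceSpec,
    test_position: int,
    reserved: Sequence[GridLocation],
    seed: int,
) -> MiniBlock:
    """A derived list isolating the position-item cue.

    The fixed-sequence item learned at ``test_position`` (1-based) appears
    there again, surrounded by never-trained locations, so its learned
    predecessor cannot precede it and only serial-position knowledge can
    speed the search.
    """
    if not 1 <= test_position <= SEQ_LEN:
        raise ValueError("test_position must be 1..4")
    test_item = fixed.items[test_position - 1]
    rng = _rng(seed, 401, test_item.cell_index)
    for _ in range(_RETRY_CAP):
        fillers = [reserved[i] for i in rng.choice(len(reserved), size=3, replace=False)]
        locs = list(fillers)
        locs.insert(test_position - 1, test_item)
        if _no_adjacent_pairs(locs):
            tags = ["new_location"] * SEQ_LEN
            tags[test_position - 1] = "ordinal_test"
            return MiniBlock("ordinal_only", tuple(locs), tuple(tags), fixed.role)
    raise RuntimeError("could not build an ordinal-only mini-block")


def _order_only_configs(
    s: SequenceSpec, o: SequenceSpec
) -> list[tuple[int, int, int, tuple[GridLocation, ...]]]:
    """Enumerate valid order-only layouts for transition sequence ``s`` and
    other sequence ``o``.

    Returns (transition_index, o_slot, z_index, locations) tuples where the
    preserved transition is ``s.items[t] -> s.items[t+1]``.  Constraints: the
    three ``s`` items sit at wrong serial positions, the single ``o`` item at
    its correct (non-first) position, exactly one learned transition occurs,
    and no consecutive pair is grid-adjacent.
    """
    pos_of = {loc: i for i, loc in enumerate(s.items)}
    pos_of.update({loc: i for i, loc in enumerate(o.items)})
    trans = set(zip(s.items, s.items[1:])) | set(zip(o.items, o.items[1:]))
    configs = []
    for t in range(SEQ_LEN - 1):
        x, y = s.items[t], s.items[t + 1]
        for q in range(SEQ_LEN - 1):  # pair occupies slots q, q+1 (0-based)
            if pos_of[x] == q or pos_of[y] == q + 1:
                continue
            free = [sl for sl in range(SEQ_LEN) if sl not in (q, q + 1)]
            for o_slot in free:
                if o_slot == 0:
                    # an item opening the list at its learned first position is
                    # a position-item probe, not wanted here
                    continue
                o_item = o.items[o_slot]
                (z_slot,) = [sl for sl in free if sl != o_slot]
                for zi, z in enumerate(s.items):
                    if z in (x, y) or pos_of[z] == z_slot:
                        continue
                    locs: list[Optional[GridLocation]] = [None] * SEQ_LEN
                    locs[q], locs[q + 1] = x, y
                    locs[o_slot], locs[z_slot] = o_item, z
                    seq = tuple(locs)  # type: ignore[arg-type]
                    n_trans = sum(p in trans for p in zip(seq, seq[1:]))
                    if n_trans == 1 and _no_adjacent_pairs(seq):
                        configs.append((t, o_slot, zi, seq))
    return configs


def make_order_only_miniblock(
    fixed1: SequenceSpec,
    fixed2: SequenceSpec,
    seed: int,
    transition_role: Optional[str] = None,
    transition_index: Optional[int] = None,
) -> MiniBlock:
    """A derived list isolating the item-item cue.

    Exactly one learned transition X -> Y is preserved, with Y (the
    order-only test trial) at a wrong serial position; the remaining slots
    hold another item of the same sequence at a wrong position and one item
    of the other sequence at its correct position.  Control trials (trained
    item at wrong position preceded by a trained non-predecessor) arise as a
    by-product and are tagged during classification.
    """
    rng = _rng(seed, 503)
    candidates = []
    for s, o in ((fixed1, fixed2), (fixed2, fixed1)):
        if transition_role is not None and s.role != transition_role:
            continue
        for cfg in _order_only_configs(s, o):
            if transition_index is not None and cfg[0] != transition_index:
                continue
            candidates.append((s, cfg))
    if not candidates:
        raise RuntimeError("no valid order-only layout for these sequences")
    s, (t, o_slot, zi, seq) = candidates[int(rng.integers(len(candidates)))]
    pos_of: dict[GridLocation, int] = {}
    pred_of: dict[GridLocation, GridLocation] = {}
    for fs in (fixed1, fixed2):
        for i, loc in enumerate(fs.items):
            pos_of[loc] = i + 1
            if i > 0:
                pred_of[loc] = fs.items[i - 1]
    tags = []
    for i, loc in enumerate(seq):
        at_pos = pos_of[loc] == i + 1
        pred = seq[i - 1] if i > 0 else None
        if pred is not None and pred_of.get(loc) == pred and not at_pos:
            tags.append("order_test")
        elif pred is not None and not at_pos:
            # trained item, wrong position, trained non-predecessor before it
            tags.append("control_test")
        else:
            tags.append("plain")
    return MiniBlock("order_only", seq, tuple(tags), s.role)


def make_transfer_block(
    spec: DesignSpec,
    sequences: dict[str, SequenceSpec],
    reserved: Sequence[GridLocation],
    seed: int,
) -> list[MiniBlock]:
    """One transfer block: 8 ordinal-only, 8 order-only, 8 random-transfer
    mini-blocks, interleaved under the run-length constraint.

    Each of the eight fixed-sequence items serves once as the ordinal test
    item; order-only transitions alternate between the two fixed sequences
    and rotate through the three transitions of each.
    """
    rng = _rng(seed, 601)
    comp = spec.transfer_composition
    pool: list[MiniBlock] = []
    labels: list[str] = []

    # ordinal-only: every fixed item once, at its learned position
    n_ord = comp.get("ordinal_only", 0)
    slots = [(role, p) for role in FIXED_ROLES for p in range(1, SEQ_LEN + 1)]
    for i in range(n_ord):
        role, pos = slots[i % len(slots)]
        mb = make_ordinal_only_miniblock(
            sequences[role], pos, reserved, int(rng.integers(2**31))
        )
        pool.append(mb)
        labels.append("ordinal_only")

    # order-only: alternate sequences, rotate transitions
    n_oo = comp.get("order_only", 0)
    t_offset = int(rng.integers(SEQ_LEN - 1))
    for i in range(n_oo):
        role = FIXED_ROLES[i % len(FIXED_ROLES)]
        t_idx = (i // len(FIXED_ROLES) + t_offset) % (SEQ_LEN - 1)
        try:
            mb = make_order_only_miniblock(
                sequences["fixed1"], sequences["fixed2"],
                int(rng.integers(2**31)),
                transition_role=role, transition_index=t_idx,
            )
        except RuntimeError:
            # this particular transition admits no layout; fall back to any
            mb = make_order_only_miniblock(
                sequences["fixed1"], sequences["fixed2"],
                int(rng.integers(2**31)), transition_role=role,
            )
        pool.append(mb)
        labels.append("order_only")

    # random transfer: mirror training random mini-blocks
    n_rt = comp.get("random_transfer", 0)
    for i in range(n_rt):
        role = RANDOM_ROLES[i % len(RANDOM_ROLES)]
        mb = _random_order_miniblock(sequences[role], "random_transfer", rng)
        pool.append(mb)
        labels.append("random_transfer")

    order = _interleave(labels, spec.max_same_condition_run, rng)
    return [pool[i] for i in order]


def assign_response_sides(
    miniblocks: list[MiniBlock], seed: int
) -> list[str]:
    """Half left, half right responses across the block, seed-shuffled.

    Returns one side per trial, in trial order.  Balance is enforced per
    block only; no within-mini-block constraint."""
    n = sum(len(mb.locations) for mb in miniblocks)
    if n % 2:
        raise ValueError("response sides need an even trial count")
    rng = _rng(seed, 701)
    sides = np.array(["left", "right"]).repeat(n // 2)
    rng.shuffle(sides)
    return [str(s) for s in sides]


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

def make_experiment(spec: DesignSpec) -> pd.DataFrame:
    """Generate the full 3-session trial table for one participant.

    Returns a long-format DataFrame, one row per trial, with rt_ms/correct
    left empty for the simulator or real data to fill.
    """
    spec.validate()
    sequences, reserved = assign_location_sets(spec)
    rows = []
    for session in range(1, spec.n_sessions + 1):
        for block in range(1, spec.blocks_per_session + 1):
            bseed = int(_rng(spec.seed, spec.participant, session, block).integers(2**31))
            if block in spec.transfer_block_positions:
                mbs = make_transfer_block(spec, sequences, reserved, bseed)
            else:
                mbs = make_training_block(spec, sequences, bseed)
            sides = assign_response_sides(mbs, bseed)
            it = iter(sides)
            for mb_i, mb in enumerate(mbs, start=1):
                for sp, (loc, tag) in enumerate(zip(mb.locations, mb.tags), start=1):
                    rows.append(
                        (
                            spec.participant, session, block, mb_i, sp,
                            mb.condition, mb.sequence_role or "",
                            loc.cell_index, loc.row, loc.col,
                            next(it), tag, np.nan, np.nan,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "participant", "session", "block", "mini_block", "serial_position",
            "condition", "sequence_role", "location", "row", "col",
            "response_side", "tag", "rt_ms", "correct",
        ],
    )


def classify_transfer_trials(
    trials: pd.DataFrame, fixed1: SequenceSpec, fixed2: SequenceSpec
) -> pd.DataFrame:
    """Recompute analysis tags for transfer trials from first principles and
    verify them against the generator's tags.

    Rules (fixed-sequence items only; random-set items carry no sequential
    structure and stay ``plain``):

    * ``new_location`` — a location outside both fixed sequences in an
      ordinal-only mini-block (never trained);
    * ``ordinal_test`` — trained item at its learned serial position whose
      predecessor is absent or untrained (hence not its learned predecessor);
    * ``order_test`` — trained item preceded by its learned predecessor
      (same sequence) but at a wrong serial position;
    * ``control_test`` — trained item at a wrong position preceded by a
      trained item that is not its learned predecessor.

    Raises ``ValueError`` naming the first trial whose recomputed tag
    disagrees with the generated one.
    """
    learned_pos = {}
    learned_pred = {}
    fixed_cells = set()
    for seq in (fixed1, fixed2):
        cells = [loc.cell_index for loc in seq.items]
        fixed_cells.update(cells)
        for i, c in enumerate(cells):
            learned_pos[c] = i + 1
            if i > 0:
                learned_pred[c] = cells[i - 1]

    out = trials.copy()
    transfer_conditions = {"ordinal_only", "order_only", "random_transfer"}
    new_tags = out["tag"].to_numpy(dtype=object).copy()

    t = out[out["condition"].isin(transfer_conditions)]
    grouped = t.groupby(["participant", "session", "block", "mini_block"], sort=False)
    for _, mb in grouped:
        mb = mb.sort_values("serial_position")
        cond = mb["condition"].iloc[0]
        cells = mb["location"].tolist()
        for i, (idx, rowd) in enumerate(mb.iterrows()):
            c = cells[i]
            pred = cells[i - 1] if i > 0 else None
            if cond == "random_transfer":
                tag = "plain"
            elif c not in fixed_cells:
                tag = "new_location"
            else:
                at_pos = learned_pos[c] == rowd["serial_position"]
                pred_fixed = pred in fixed_cells if pred is not None else False
                pred_learned = pred is not None and learned_pred.get(c) == pred
                if at_pos and not pred_fixed:
                    tag = "ordinal_test"
                elif pred_learned and not at_pos:
                    tag = "order_test"
                elif pred_fixed and not pred_learned and not at_pos:
                    tag = "control_test"
                else:
                    tag = "plain"
            gen = rowd["tag"]
            if tag != gen:
                raise ValueError(
                    f"tag mismatch at trial index {idx}: generated {gen!r}, "
                    f"recomputed {tag!r}"
                )
            new_tags[out.index.get_loc(idx)] = tag
    out["tag"] = new_tags
    return out
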