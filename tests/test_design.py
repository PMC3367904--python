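"""Trial-structure generation: grid, sequences, blocks, tags."""

import numpy as np
import pytest

from serialorder.design import (
    DesignSpec,
    GridLocation,
    SequenceSpec,
    assign_location_sets,
    assign_response_sides,
    classify_transfer_trials,
    is_adjacent,
    make_experiment,
    make_fixed_sequence,
    make_grid,
    make_order_only_miniblock,
    make_ordinal_only_miniblock,
    make_training_block,
    make_transfer_block,
)

GRID = make_grid()
BY_RC = {(g.row, g.col): g for g in GRID}


class TestGrid:
    def test_32_locations_without_corners(self):
        assert len(GRID) == 32
        coords = {(g.row, g.col) for g in GRID}
        assert len(coords) == 32
        for corner in [(0, 0), (0, 5), (5, 0), (5, 5)]:
            assert corner not in coords

    def test_mid_grid_cell_has_eight_neighbors(self):
        center = BY_RC[(2, 2)]
        neighbors = [g for g in GRID if g != center and is_adjacent(center, g)]
        expected = {
            (r, c)
            for r in (1, 2, 3)
            for c in (1, 2, 3)
            if (r, c) != (2, 2)
        }
        assert {(g.row, g.col) for g in neighbors} == expected

    @pytest.mark.parametrize(
        "a,b,adj",
        [((2, 2), (2, 3), True), ((2, 2), (3, 3), True), ((0, 1), (5, 4), False)],
    )
    def test_adjacency_convention(self, a, b, adj):
        assert is_adjacent(BY_RC[a], BY_RC[b]) is adj

    def test_adjacency_rejects_identical_locations(self):
        with pytest.raises(ValueError):
            is_adjacent(BY_RC[(2, 2)], BY_RC[(2, 2)])


class TestFixedSequence:
    def test_non_adjacent_items_any_order_valid(self):
        items = [BY_RC[rc] for rc in [(0, 1), (2, 3), (4, 1), (0, 4)]]
        seq = make_fixed_sequence(items, seed=3)
        assert set(seq.items) == set(items)
        assert all(not is_adjacent(x, y) for x, y in zip(seq.items, seq.items[1:]))

    def test_adjacent_pair_never_consecutive(self):
        # (1,1)-(1,2) is the only adjacent pair in this set
        items = [BY_RC[rc] for rc in [(1, 1), (1, 2), (3, 4), (5, 1)]]
        for seed in range(10):
            seq = make_fixed_sequence(items, seed=seed)
            pairs = list(zip(seq.items, seq.items[1:]))
            assert (BY_RC[(1, 1)], BY_RC[(1, 2)]) not in pairs
            assert (BY_RC[(1, 2)], BY_RC[(1, 1)]) not in pairs

    def test_two_by_two_square_has_no_valid_ordering(self):
        items = [BY_RC[rc] for rc in [(2, 2), (2, 3), (3, 2), (3, 3)]]
        with pytest.raises(ValueError, match="no non-adjacent ordering"):
            make_fixed_sequence(items, seed=0)


class TestLocationSets:
    def test_partition_into_roles_and_reserved(self, location_sets):
        roles, reserved = location_sets
        assert len(reserved) == 16
        cells = [loc for s in roles.values() for loc in s.items] + list(reserved)
        assert len(cells) == 32 and len(set(cells)) == 32

    def test_counterbalancing_cycle(self):
        """Across 8 participants each location serves each playing role once."""
        from collections import Counter

        seen = {c: Counter() for c in range(32)}
        for p in range(1, 9):
            roles, reserved = assign_location_sets(DesignSpec(seed=5, participant=p))
            for role, s in roles.items():
                for loc in s.items:
                    seen[loc.cell_index][role] += 1
            for loc in reserved:
                seen[loc.cell_index]["reserved"] += 1
        for counts in seen.values():
            assert counts["reserved"] == 4
            for role in ("fixed1", "fixed2", "random_setA", "random_setB"):
                assert counts[role] == 1


class TestBlocks:
    def test_training_block_composition_and_runs(self, design_spec, location_sets):
        roles, _ = location_sets
        mbs = make_training_block(design_spec, roles, seed=42)
        assert sum(len(mb.locations) for mb in mbs) == 96
        conds = [mb.condition for mb in mbs]
        assert conds.count("fixed") == 16 and conds.count("random") == 8
        fixed_roles = [mb.sequence_role for mb in mbs if mb.condition == "fixed"]
        assert fixed_roles.count("fixed1") == 8 and fixed_roles.count("fixed2") == 8
        longest = max(
            len(list(g)) for _, g in __import__("itertools").groupby(conds)
        )
        assert longest <= design_spec.max_same_condition_run
        for mb in mbs:
            if mb.condition == "fixed":
                assert mb.locations == roles[mb.sequence_role].items

    def test_transfer_block_composition(self, design_spec, location_sets):
        roles, reserved = location_sets
        mbs = make_transfer_block(design_spec, roles, reserved, seed=42)
        conds = [mb.condition for mb in mbs]
        assert conds.count("ordinal_only") == 8
        assert conds.count("order_only") == 8
        assert conds.count("random_transfer") == 8
        assert sum(len(mb.locations) for mb in mbs) == 96
        # every fixed item serves exactly once as the ordinal test item
        test_items = [
            loc
            for mb in mbs
            if mb.condition == "ordinal_only"
            for loc, tag in zip(mb.locations, mb.tags)
            if tag == "ordinal_test"
        ]
        all_fixed = set(roles["fixed1"].items) | set(roles["fixed2"].items)
        assert set(test_items) == all_fixed and len(test_items) == 8

    def test_ordinal_miniblock_structure(self, location_sets):
        roles, reserved = location_sets
        fixed = roles["fixed1"]
        mb = make_ordinal_only_miniblock(fixed, test_position=3, reserved=reserved, seed=9)
        assert mb.tags[2] == "ordinal_test"
        assert mb.locations[2] == fixed.items[2]
        assert [t for t in mb.tags if t == "new_location"] == ["new_location"] * 3
        for loc, tag in zip(mb.locations, mb.tags):
            if tag == "new_location":
                assert loc in reserved

    def test_order_miniblock_structure(self, location_sets):
        roles, _ = location_sets
        f1, f2 = roles["fixed1"], roles["fixed2"]
        learned_pos = {loc: i for s in (f1, f2) for i, loc in enumerate(s.items)}
        preds = {s.items[i + 1]: s.items[i] for s in (f1, f2) for i in range(3)}
        for seed in range(12):
            mb = make_order_only_miniblock(f1, f2, seed=seed)
            assert mb.tags.count("order_test") == 1
            i = mb.tags.index("order_test")
            assert i > 0, "an order test trial needs a predecessor"
            loc = mb.locations[i]
            assert mb.locations[i - 1] == preds[loc]
            assert learned_pos[loc] != i, "test item must sit at a wrong position"

    def test_response_sides_balanced_per_block(self, design_spec, location_sets):
        roles, _ = location_sets
        mbs = make_training_block(design_spec, roles, seed=1)
        sides = assign_response_sides(mbs, seed=1)
        assert sides.count("left") == sides.count("right") == 48
        assert assign_response_sides(mbs, seed=2) != sides


class TestExperiment:
    def test_session_and_block_counts(self, design_table):
        assert len(design_table) == 54 * 96
        training = design_table[~design_table.block.isin([6, 12, 18])]
        mb = training.groupby(["session", "block", "mini_block"]).first()
        fixed1 = mb[mb.sequence_role == "fixed1"].groupby("session").size()
        assert fixed1.tolist() == [120, 120, 120]
        randA = mb[
            (mb.sequence_role == "random_setA") & (mb.condition == "random")
        ].groupby("session").size()
        assert randA.tolist() == [60, 60, 60]
        assert (design_table.groupby(["session", "block"]).size() == 96).all()

    def test_transfer_blocks_at_6_12_18(self, design_table):
        transfer = design_table[
            design_table.condition.isin(["ordinal_only", "order_only", "random_transfer"])
        ]
        assert sorted(transfer.block.unique()) == [6, 12, 18]

    def test_regeneration_is_bit_identical(self, design_spec, design_table):
        again = make_experiment(DesignSpec(seed=design_spec.seed, participant=1))
        assert again.equals(design_table)

    def test_no_adjacent_consecutive_pair_anywhere(self, design_table):
        grid = {g.cell_index: g for g in GRID}
        for _, mb in design_table.groupby(["session", "block", "mini_block"]):
            cells = mb.sort_values("serial_position").location.tolist()
            for a, b in zip(cells, cells[1:]):
                assert not is_adjacent(grid[a], grid[b])

    def test_classification_matches_generation(self, design_table, location_sets):
        roles, _ = location_sets
        out = classify_transfer_trials(design_table, roles["fixed1"], roles["fixed2"])
        assert (out.tag == design_table.tag).all()

    def test_classification_flags_corrupted_tag(self, design_table, location_sets):
        roles, _ = location_sets
        corrupted = design_table.copy()
        idx = corrupted.index[corrupted.tag == "ordinal_test"][0]
        corrupted.loc[idx, "tag"] = "order_test"
        with pytest.raises(ValueError, match="tag mismatch"):
            classify_transfer_trials(corrupted, roles["fixed1"], roles["fixed2"])

    def test_first_trial_never_order_test(self, design_table):
        firsts = design_table[design_table.serial_position == 1]
        assert not (firsts.tag == "order_test").any()
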