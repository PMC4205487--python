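"""Tests for Sankoff parsimony over the karyotype lattice."""

import io as _io
import itertools

import pytest

from karyoevo.io import KaryotypeRecord, read_newick
from karyoevo.model import EventMultiset, KaryotypeState, event_distance
from karyoevo.reconstruct import (
    ReconstructionError,
    build_state_space,
    decompose_all_branches,
    enumerate_mprs,
    reconstruct_clade,
    reconstruct_count_character,
    sankoff_reconstruct,
    select_assignment,
)

S = KaryotypeState
REF = KaryotypeState(0, 24)  # ancestral cichlid karyotype, 48st-a


def records_for(states: dict[str, S]) -> list[KaryotypeRecord]:
    return [
        KaryotypeRecord(label, s.diploid_number, s.formula, 0)
        for label, s in states.items()
    ]


class TestStateSpace:
    def test_bounds_widen_observed_range_by_slack(self):
        tips = [S(7, 18), S(8, 16), S(9, 13), S(9, 13), S(8, 14)]
        space = build_state_space(tips, slack=4)
        assert (space.m_min, space.m_max) == (3, 13)
        assert (space.a_min, space.a_max) == (9, 22)
        assert all(space.contains(t) for t in tips)

    def test_single_tip_slack_zero_is_one_state(self):
        space = build_state_space([S(5, 5)], slack=0)
        assert len(space) == 1
        assert space.states == (S(5, 5),)

    def test_minima_clip_at_zero(self):
        space = build_state_space([S(1, 2)], slack=4)
        assert space.m_min == 0 and space.a_min == 0


class TestFixtureReconstruction:
    def test_root_mpr_contains_ancestral_karyotype(
        self, fixture_tree, fixture_records
    ):
        result = sankoff_reconstruct(fixture_tree, fixture_records)
        assert S(8, 16) in result.root_states()
        assert result.total_cost == 5

    def test_root_tie_resolved_toward_reference(
        self, fixture_tree, fixture_records
    ):
        result = sankoff_reconstruct(fixture_tree, fixture_records)
        # parsimony alone leaves the root two-way ambiguous
        assert set(result.root_states()) == {S(7, 18), S(8, 16)}
        assignment = select_assignment(result, reference=REF)
        assert assignment[fixture_tree.root_id] == S(8, 16)

    def test_branch_event_scenario(self, fixture_tree, fixture_records):
        result = sankoff_reconstruct(fixture_tree, fixture_records)
        assignment = select_assignment(result, reference=REF)
        branches = decompose_all_branches(result, assignment)
        assert branches["maronii"] == EventMultiset(fissions=1)
        nannacara_stem = fixture_tree.parent_id("taenia")
        assert branches[nannacara_stem] == EventMultiset(
            fusions=2, inv_m_to_a=1
        )
        assert branches["taenia"] == EventMultiset(inv_m_to_a=1)
        assert branches["adoketa"] == EventMultiset()
        assert sum(ms.total for ms in branches.values()) == result.total_cost

    def test_slack_does_not_change_cost_once_stable(
        self, fixture_tree, fixture_records
    ):
        costs = {
            slack: sankoff_reconstruct(
                fixture_tree, fixture_records, slack=slack
            ).total_cost
            for slack in (0, 2, 6)
        }
        assert costs[0] == costs[2] == costs[6] == 5

    def test_rerooting_preserves_total_cost(self, fixture_records):
        for reroot_leaf in ("anomala", "adoketa"):
            tree = read_newick(
                _io.StringIO(
                    "((((anomala,aureocephalus),taenia),adoketa),maronii);"
                )
            )
            node = tree.node(reroot_leaf)
            tree.tree.reroot_at_edge(node.edge)
            rerooted = type(tree)(tree.tree)
            result = sankoff_reconstruct(rerooted, fixture_records)
            assert result.total_cost == 5

    def test_leaf_without_record_raises(self, fixture_tree, fixture_records):
        with pytest.raises(Exception, match="taenia"):
            sankoff_reconstruct(
                fixture_tree,
                [r for r in fixture_records if "taenia" not in r.species],
            )


class TestSmallTreeOracles:
    def test_single_leaf_equivalent_root_is_leaf_state(self):
        tree = read_newick(_io.StringIO("(a,b);"))
        state = S(4, 6)
        result = sankoff_reconstruct(
            tree, records_for({"a": state, "b": state}), slack=1
        )
        assert result.total_cost == 0
        assert result.root_states() == (state,)

    @pytest.mark.parametrize(
        "s1, s2",
        [(S(8, 16), S(7, 18)), (S(8, 16), S(9, 13)), (S(3, 3), S(3, 3))],
    )
    def test_two_leaf_cost_is_pairwise_distance(self, s1, s2):
        tree = read_newick(_io.StringIO("(a,b);"))
        result = sankoff_reconstruct(
            tree, records_for({"a": s1, "b": s2}), slack=2
        )
        assert result.total_cost == event_distance(s1, s2)

    def test_agrees_with_exhaustive_enumeration_on_four_leaves(self):
        tree = read_newick(_io.StringIO("((a,b),(c,d));"))
        tips = {"a": S(4, 6), "b": S(5, 4), "c": S(3, 7), "d": S(4, 5)}
        space = build_state_space(list(tips.values()), slack=1)
        states = space.states
        assert len(states) <= 40
        result = sankoff_reconstruct(tree, records_for(tips), space=space)

        # independent oracle: enumerate every internal-node assignment
        left = "N2"
        best_cost = float("inf")
        for sr, sl, sq in itertools.product(states, repeat=3):
            cost = event_distance(sr, sl) + event_distance(sr, sq)
            for leaf, tip_state in tips.items():
                parent = tree.parent_id(leaf)
                parent_state = sl if parent == left else sq
                cost += event_distance(parent_state, tip_state)
            best_cost = min(best_cost, cost)
        assert result.total_cost == best_cost


class TestMprEnumeration:
    def test_fixture_has_exactly_two_optimal_assignments(
        self, fixture_tree, fixture_records
    ):
        result = sankoff_reconstruct(fixture_tree, fixture_records)
        assignments, truncated = enumerate_mprs(result)
        assert not truncated
        assert len(assignments) == 2
        roots = {a[fixture_tree.root_id] for a in assignments}
        assert roots == {S(7, 18), S(8, 16)}
        for assignment in assignments:
            total = sum(
                event_distance(
                    assignment[fixture_tree.parent_id(n)], assignment[n]
                )
                for n in fixture_tree.preorder_ids()
                if fixture_tree.parent_id(n) is not None
            )
            assert total == result.total_cost

    def test_cap_truncates_with_flag(self, fixture_tree, fixture_records):
        result = sankoff_reconstruct(fixture_tree, fixture_records)
        assignments, truncated = enumerate_mprs(result, cap=1)
        assert truncated and len(assignments) == 1

    def test_tied_two_leaf_case_enumerates_all_equal_cost_roots(self):
        tree = read_newick(_io.StringIO("(a,b);"))
        s1, s2 = S(5, 5), S(7, 5)
        result = sankoff_reconstruct(
            tree, records_for({"a": s1, "b": s2}), slack=2
        )
        assignments, _ = enumerate_mprs(result)
        costs = set()
        for assignment in assignments:
            costs.add(
                event_distance(assignment["N1"], s1)
                + event_distance(assignment["N1"], s2)
            )
        assert costs == {result.total_cost}
        assert len(assignments) >= 2

    def test_inconsistent_assignment_rejected(
        self, fixture_tree, fixture_records
    ):
        result = sankoff_reconstruct(fixture_tree, fixture_records)
        assignment = select_assignment(result, reference=REF)
        assignment["maronii"] = S(0, 2)
        with pytest.raises(ReconstructionError):
            decompose_all_branches(result, assignment)


class TestCountCharacter:
    def test_fixture_cma3_root_is_one_pair_cost_two(
        self, fixture_tree, fixture_records
    ):
        counts = {
            "maronii": 1,
            "adoketa": 1,
            "taenia": 1,
            "anomala": 1,
            "aureocephalus": 3,
        }
        result = reconstruct_count_character(fixture_tree, counts)
        assert result.root_states() == (1,)
        assert result.total_cost == 2

    def test_constant_counts_cost_zero(self, fixture_tree):
        counts = {leaf: 2 for leaf in fixture_tree.leaf_labels}
        result = reconstruct_count_character(fixture_tree, counts)
        assert result.total_cost == 0
        assert result.root_states() == (2,)

    def test_two_leaf_gradient_all_intermediates_optimal(self):
        tree = read_newick(_io.StringIO("(a,b);"))
        result = reconstruct_count_character(tree, {"a": 0, "b": 4})
        assert result.total_cost == 4
        assert result.root_states() == (0, 1, 2, 3, 4)


class TestCladePipeline:
    def test_combined_cost_sums_characters(self, fixture_tree, fixture_records):
        result = reconstruct_clade(
            fixture_tree, fixture_records, reference=REF
        )
        assert result.combined_cost == 5 + 2
        assert result.root_state == S(8, 16)
        assert result.root_cma3 == 1

    def test_clade_restriction_prunes_outgroup(self, fixture_records):
        tree = read_newick(
            _io.StringIO(
                "(((((anomala,aureocephalus),taenia),adoketa),maronii),outgroup);"
            )
        )
        result = reconstruct_clade(
            tree,
            fixture_records,
            reference=REF,
            include_cma3=False,
            clade=["anomala", "maronii"],
        )
        assert sorted(result.tree.leaf_labels) == [
            "adoketa",
            "anomala",
            "aureocephalus",
            "maronii",
            "taenia",
        ]
        assert result.karyotype.total_cost == 5
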