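"""Unit and property tests for the karyotype event algebra."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from karyoevo.model import (
    EventKind,
    EventMultiset,
    FeasibilityError,
    FormulaError,
    KaryotypeState,
    UnreachableError,
    apply_event,
    decompose_minimal_events,
    event_distance,
    format_karyotype_formula,
    min_event_path,
    parse_karyotype_formula,
)

S = KaryotypeState

lattice_states = st.builds(
    S,
    biarmed_pairs=st.integers(0, 12),
    uniarmed_pairs=st.integers(0, 25),
)
# states connected on the lattice: the empty karyotype is isolated
nonempty_states = lattice_states.filter(lambda s: s.pair_number > 0)


class TestFormulaParsing:
    @pytest.mark.parametrize(
        "text, m, a",
        [
            ("16m-sm+32st-a", 8, 16),
            ("14sm+36st-a", 7, 18),
            ("2m-sm+2st-a", 1, 1),
            ("18m-sm+26st-a", 9, 13),
            ("4m+6sm+10st+8a", 5, 9),  # fine-grained categories pool
            ("48st-a", 0, 24),
            ("10M-SM+2T", 5, 1),  # case-insensitive
        ],
    )
    def test_parses_to_pair_counts(self, text, m, a):
        state = parse_karyotype_formula(text)
        assert (state.biarmed_pairs, state.uniarmed_pairs) == (m, a)
        assert state.diploid_number == 2 * (m + a)

    @pytest.mark.parametrize(
        "text",
        ["15m-sm+29st-a", "16m-sm+foo", "m-sm+26st-a", "", "16q+32st-a"],
    )
    def test_rejects_bad_formulas(self, text):
        with pytest.raises(FormulaError):
            parse_karyotype_formula(text)

    def test_lenient_mode_floors_odd_counts_with_warning(self):
        with pytest.warns(UserWarning):
            state = parse_karyotype_formula("15m-sm+29st-a", lenient=True)
        assert (state.biarmed_pairs, state.uniarmed_pairs) == (7, 14)

    @given(lattice_states)
    def test_canonical_roundtrip(self, state):
        text = format_karyotype_formula(state)
        assert parse_karyotype_formula(text).drop_cma3() == state


class TestApplyEvent:
    def test_fusion_fission_move_2n_by_two(self):
        s = S(8, 16)
        assert apply_event(s, EventKind.FUSION) == S(9, 14)
        assert apply_event(s, EventKind.FISSION) == S(7, 18)
        assert apply_event(s, EventKind.FUSION).diploid_number == 46
        assert apply_event(s, EventKind.FISSION).diploid_number == 50

    def test_inversions_preserve_2n(self):
        s = S(8, 16)
        for ev in (EventKind.INV_M_TO_A, EventKind.INV_A_TO_M):
            assert apply_event(s, ev).diploid_number == s.diploid_number

    @pytest.mark.parametrize(
        "state, event",
        [
            (S(0, 1), EventKind.FUSION),
            (S(0, 5), EventKind.FISSION),
            (S(0, 5), EventKind.INV_M_TO_A),
            (S(5, 0), EventKind.INV_A_TO_M),
            (S(5, 5, 0), EventKind.CMA3_LOSS),
            (S(1, 1, 2), EventKind.CMA3_GAIN),
            (S(5, 5), EventKind.CMA3_GAIN),  # CMA3 not tracked
        ],
    )
    def test_infeasible_events_raise(self, state, event):
        with pytest.raises(FeasibilityError):
            apply_event(state, event)

    def test_input_state_unmodified(self):
        s = S(8, 16, 1)
        apply_event(s, EventKind.FUSION)
        assert s == S(8, 16, 1)

    @given(nonempty_states, st.sampled_from(list(EventKind)[:4]))
    def test_event_then_inverse_is_identity(self, state, event):
        from karyoevo.model import INVERSE

        try:
            moved = apply_event(state, event)
        except FeasibilityError:
            return
        try:
            back = apply_event(moved, INVERSE[event])
        except FeasibilityError:
            return
        assert back == state

    @given(nonempty_states, st.lists(st.sampled_from(list(EventKind)[:4]), max_size=12))
    def test_parity_of_2n_conserved(self, state, events):
        for ev in events:
            try:
                state = apply_event(state, ev)
            except FeasibilityError:
                continue
            assert state.diploid_number % 2 == 0


class TestEventDistance:
    @pytest.mark.parametrize(
        "s1, s2, d",
        [
            (S(8, 16), S(8, 16), 0),
            (S(8, 16), S(7, 18), 1),  # one fission
            (S(8, 16), S(9, 13), 3),  # two fusions + one inversion
            (S(9, 13), S(8, 14), 1),  # one pericentric inversion
            (S(0, 2), S(1, 0), 1),
        ],
    )
    def test_known_distances(self, s1, s2, d):
        assert event_distance(s1, s2) == d

    def test_cma3_component_adds_absolute_difference(self):
        assert event_distance(S(8, 16, 1), S(8, 16, 3)) == 2
        assert event_distance(S(8, 16, 1), S(9, 13, 3)) == 5

    def test_empty_karyotype_is_unreachable(self):
        assert event_distance(S(0, 0), S(1, 0)) == math.inf
        assert event_distance(S(0, 0), S(0, 0)) == 0

    @given(nonempty_states, nonempty_states)
    def test_symmetry(self, s1, s2):
        assert event_distance(s1, s2) == event_distance(s2, s1)

    @given(nonempty_states, nonempty_states, nonempty_states)
    def test_triangle_inequality(self, s1, s2, s3):
        assert event_distance(s1, s3) <= event_distance(s1, s2) + event_distance(
            s2, s3
        )

    @given(nonempty_states)
    def test_identity(self, s):
        assert event_distance(s, s) == 0

    @given(nonempty_states, nonempty_states)
    def test_agrees_with_bfs_oracle(self, s1, s2):
        assert event_distance(s1, s2) == len(min_event_path(s1, s2))


class TestDecomposition:
    @pytest.mark.parametrize(
        "s1, s2, expected",
        [
            (S(8, 16), S(7, 18), EventMultiset(fissions=1)),
            (S(8, 16), S(9, 13), EventMultiset(fusions=2, inv_m_to_a=1)),
            (S(5, 5), S(5, 5), EventMultiset()),
            (S(9, 13), S(8, 14), EventMultiset(inv_m_to_a=1)),
            (S(8, 16, 1), S(9, 13, 3), EventMultiset(fusions=2, inv_m_to_a=1, cma3_gains=2)),
        ],
    )
    def test_known_decompositions(self, s1, s2, expected):
        assert decompose_minimal_events(s1, s2) == expected

    @given(nonempty_states, nonempty_states)
    def test_minimal_and_totals_to_distance(self, s1, s2):
        ms = decompose_minimal_events(s1, s2)
        assert ms.is_minimal()
        assert ms.total == event_distance(s1, s2)

    def test_unreachable_raises(self):
        with pytest.raises(UnreachableError):
            decompose_minimal_events(S(1, 0), S(0, 0))


class TestMinEventPath:
    def test_identity_is_empty(self):
        assert min_event_path(S(8, 16), S(8, 16)) == []

    def test_length_three_path_multiset(self):
        path = min_event_path(S(8, 16), S(9, 13))
        assert len(path) == 3
        assert EventMultiset.from_events(path) == EventMultiset(
            fusions=2, inv_m_to_a=1
        )

    def test_only_feasible_single_event(self):
        assert min_event_path(S(0, 2), S(1, 0)) == [EventKind.FUSION]

    def test_path_replays_through_feasible_states(self):
        s = S(3, 4, 2)
        target = S(6, 0, 1)
        path = min_event_path(s, target)
        state = s
        for ev in path:
            state = apply_event(state, ev)  # raises if infeasible
        assert state == target

    def test_unreachable_target(self):
        with pytest.raises(UnreachableError):
            min_event_path(S(1, 0), S(0, 0), bounds=(2, 2))
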