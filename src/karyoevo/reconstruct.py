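"""Ancestral karyotype reconstruction by generalized (Sankoff) parsimony.

The transition cost between two karyotypes is the minimal number of
rearrangement events separating them (:func:`karyoevo.model.event_distance`),
so the parsimony score of a labelled tree is the total event count its
history requires.  Dynamic programming runs post-order over a bounded
lattice of candidate states; a pre-order sweep marks every state that
participates in at least one most-parsimonious reconstruction (MPR).

The CMA3 signal-pair count is reconstructed as an independent ordered
character with unit cost per gain or loss; a combined analysis simply sums
the two characters' costs, since their events are distinct.

Because event counting is symmetric, a rooted ingroup tree alone can leave
the root state ambiguous (several root states reach the same total).  The
study context resolves this the way comparative cytogenetics does: among
tied root states, prefer the one fewest events away from a *reference*
(outgroup-informed) karyotype — here, the ancestral cichlid karyotype of
48 uniarmed chromosomes.  The tie-break selects among exact co-optima only;
it never changes the parsimony score.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .io import AnnotatedTree, KaryotypeRecord, match_records_to_leaves
from .model import (
    EventMultiset,
    KaryotypeError,
    KaryotypeState,
    decompose_minimal_events,
    event_distance,
)

__all__ = [
    "StateSpace",
    "build_state_space",
    "ReconstructionResult",
    "sankoff_reconstruct",
    "reconstruct_count_character",
    "enumerate_mprs",
    "decompose_all_branches",
    "select_assignment",
    "CladeReconstruction",
    "reconstruct_clade",
]


class ReconstructionError(KaryotypeError):
    """Invalid input to, or inconsistent use of, a reconstruction."""


@dataclass(frozen=True)
class StateSpace:
    """Bounded rectangle of candidate karyotype states (pair units)."""

    m_min: int
    m_max: int
    a_min: int
    a_max: int

    def __post_init__(self) -> None:
        if self.m_min < 0 or self.a_min < 0:
            raise ReconstructionError("state-space bounds must be non-negative")
        if self.m_max < self.m_min or self.a_max < self.a_min:
            raise ReconstructionError("empty state space")

    @property
    def states(self) -> tuple[KaryotypeState, ...]:
        return tuple(
            KaryotypeState(m, a)
            for m in range(self.m_min, self.m_max + 1)
            for a in range(self.a_min, self.a_max + 1)
        )

    def __len__(self) -> int:
        return (self.m_max - self.m_min + 1) * (self.a_max - self.a_min + 1)

    def contains(self, state: KaryotypeState) -> bool:
        return (
            self.m_min <= state.biarmed_pairs <= self.m_max
            and self.a_min <= state.uniarmed_pairs <= self.a_max
        )


def build_state_space(
    tips: Sequence[KaryotypeState], slack: int = 4
) -> StateSpace:
    """Bound the candidate lattice by the observed tip range widened by ``slack``.

    The per-axis minima are clipped at zero.  The default slack of 4 pairs
    comfortably contains geodesic intermediates for karyotypes as divergent
    as those seen within a genus; widening further never changes the
    parsimony score once all geodesics fit.
    """
    if not tips:
        raise ReconstructionError("state space needs at least one tip state")
    if slack < 0:
        raise ReconstructionError("slack must be non-negative")
    ms = [s.biarmed_pairs for s in tips]
    as_ = [s.uniarmed_pairs for s in tips]
    return StateSpace(
        m_min=max(0, min(ms) - slack),
        m_max=max(ms) + slack,
        a_min=max(0, min(as_) - slack),
        a_max=max(as_) + slack,
    )


# --------------------------------------------------------------------------
# Cost matrices

def karyotype_cost_matrix(states: Sequence[KaryotypeState]) -> np.ndarray:
    """Pairwise event distances between states, as a float matrix.

    Vectorized closed form ``|dN| + |dM + dN|``.  The forced minimal
    multiset always admits a feasible ordering except when exactly one
    endpoint is the isolated empty karyotype (0, 0) (verified exhaustively
    against the BFS oracle in the test suite), so those entries are set to
    infinity and everything else is the closed form.
    """
    m = np.array([s.biarmed_pairs for s in states])
    a = np.array([s.uniarmed_pairs for s in states])
    dn = (m[None, :] + a[None, :]) - (m[:, None] + a[:, None])
    dk = (m[None, :] - m[:, None]) + dn
    cost = (np.abs(dn) + np.abs(dk)).astype(float)
    empty = (m + a) == 0
    if empty.any():
        one_sided = empty[:, None] != empty[None, :]
        cost[one_sided] = np.inf
    return cost


# --------------------------------------------------------------------------
# Generic Sankoff engine

@dataclass
class ReconstructionResult:
    """Outcome of a Sankoff parsimony run for one character.

    Attributes
    ----------
    tree:
        The tree the reconstruction ran on.
    states:
        The ordered candidate state list (lattice states or integer counts).
    cost_tables:
        Per-node vector of subtree costs conditional on the node's state.
    mpr_sets:
        Per-node tuple of states occurring in at least one MPR, in
        deterministic ascending order.
    total_cost:
        Minimum total event count over the tree.
    character:
        ``"karyotype"`` or ``"cma3"``; controls branch decomposition.
    """

    tree: AnnotatedTree
    states: tuple
    cost_tables: dict[str, np.ndarray]
    mpr_sets: dict[str, tuple]
    total_cost: float
    character: str
    _cost_matrix: np.ndarray = field(repr=False)
    _state_index: dict = field(repr=False)

    def root_states(self) -> tuple:
        """The MPR set at the root."""
        return self.mpr_sets[self.tree.root_id]

    def child_options(self, child_id: str, parent_state) -> tuple:
        """States of ``child_id`` optimal beneath a parent fixed to ``parent_state``."""
        p = self._state_index[parent_state]
        vec = self._cost_matrix[p] + self.cost_tables[child_id]
        best = vec.min()
        return tuple(
            self.states[k] for k in np.nonzero(vec == best)[0]
        )


def _sankoff(
    tree: AnnotatedTree,
    leaf_state: Mapping[str, object],
    states: Sequence,
    cost_matrix: np.ndarray,
    character: str,
) -> ReconstructionResult:
    n = len(states)
    index = {s: i for i, s in enumerate(states)}
    for leaf, st in leaf_state.items():
        if st not in index:
            raise ReconstructionError(
                f"tip state {st} of leaf {leaf!r} lies outside the state space"
            )
    cost_tables: dict[str, np.ndarray] = {}
    order = tree.preorder_ids()
    for node_id in reversed(order):
        if tree.is_leaf(node_id):
            if node_id not in leaf_state:
                raise ReconstructionError(
                    f"leaf {node_id!r} has no character state"
                )
            vec = np.full(n, np.inf)
            vec[index[leaf_state[node_id]]] = 0.0
        else:
            vec = np.zeros(n)
            for child in tree.children_ids(node_id):
                child_vec = cost_tables[child]
                vec += (cost_matrix + child_vec[None, :]).min(axis=1)
        cost_tables[node_id] = vec
    root_vec = cost_tables[tree.root_id]
    total = float(root_vec.min())
    # pre-order marking of states participating in >= 1 optimal assignment
    marked: dict[str, np.ndarray] = {}
    marked[tree.root_id] = root_vec == total
    for node_id in order:
        mask = marked[node_id]
        for child in tree.children_ids(node_id):
            child_vec = cost_tables[child]
            child_mask = np.zeros(n, dtype=bool)
            for p in np.nonzero(mask)[0]:
                vec = cost_matrix[p] + child_vec
                child_mask |= vec == vec.min()
            marked[child] = child_mask
    mpr_sets = {
        node_id: tuple(states[k] for k in np.nonzero(marked[node_id])[0])
        for node_id in order
    }
    if float(total).is_integer():
        total = int(total)
    return ReconstructionResult(
        tree=tree,
        states=tuple(states),
        cost_tables=cost_tables,
        mpr_sets=mpr_sets,
        total_cost=total,
        character=character,
        _cost_matrix=cost_matrix,
        _state_index=index,
    )


def sankoff_reconstruct(
    tree: AnnotatedTree,
    records: Sequence[KaryotypeRecord],
    space: StateSpace | None = None,
    slack: int = 4,
) -> ReconstructionResult:
    """Reconstruct ancestral arm-class karyotypes on a rooted tree.

    Leaf states come from the records' karyotype formulas (matched to leaf
    labels, full species names allowed); candidate ancestral states span
    ``space`` (built from the tips with ``slack`` if not given).  Branch
    lengths, if any, are ignored: the criterion is event-count parsimony.
    """
    leaf_records = match_records_to_leaves(tree, records)
    leaf_state = {
        leaf: rec.state(include_cma3=False)
        for leaf, rec in leaf_records.items()
    }
    if space is None:
        space = build_state_space(list(leaf_state.values()), slack=slack)
    states = space.states
    cost = karyotype_cost_matrix(states)
    return _sankoff(tree, leaf_state, states, cost, character="karyotype")


def reconstruct_count_character(
    tree: AnnotatedTree,
    counts: Mapping[str, int],
    max_count: int | None = None,
) -> ReconstructionResult:
    """Reconstruct an ordered count character (CMA3 signal pairs).

    Sankoff parsimony with cost ``|dc|`` over the states ``0..max_count``
    (default: observed maximum + 2).
    """
    if not counts:
        raise ReconstructionError("no leaf counts given")
    for leaf, c in counts.items():
        if c < 0:
            raise ReconstructionError(f"negative count {c} for leaf {leaf!r}")
    if max_count is None:
        max_count = max(counts.values()) + 2
    if max_count < max(counts.values()):
        raise ReconstructionError("max_count below an observed count")
    states = tuple(range(max_count + 1))
    grid = np.arange(max_count + 1)
    cost = np.abs(grid[:, None] - grid[None, :]).astype(float)
    return _sankoff(tree, dict(counts), states, cost, character="cma3")


# --------------------------------------------------------------------------
# MPR assignments

def _sorted_states(result: ReconstructionResult, states: Iterable) -> list:
    if result.character == "karyotype":
        return sorted(states, key=lambda s: s.sort_key())
    return sorted(states)


def select_assignment(
    result: ReconstructionResult,
    reference: KaryotypeState | None = None,
) -> dict[str, object]:
    """Deterministically select one MPR assignment.

    The root state is chosen among the root MPR set by (when given)
    smallest event distance to ``reference`` and then lexicographic order;
    descendant states are filled in greedily in preorder, taking the
    lexicographically smallest optimal state under the chosen parent.  With
    ``reference=None`` this is exactly the lexicographically smallest MPR.
    """
    tree = result.tree
    root_choices = _sorted_states(result, result.root_states())
    if reference is not None and result.character == "karyotype":
        root_choices.sort(
            key=lambda s: (event_distance(s, reference), s.sort_key())
        )
    assignment: dict[str, object] = {tree.root_id: root_choices[0]}
    for node_id in tree.preorder_ids():
        parent_state = assignment[node_id]
        for child in tree.children_ids(node_id):
            options = _sorted_states(
                result, result.child_options(child, parent_state)
            )
            assignment[child] = options[0]
    return assignment


def enumerate_mprs(
    result: ReconstructionResult, cap: int = 10000
) -> tuple[list[dict[str, object]], bool]:
    """Enumerate all most-parsimonious full node-state assignments.

    Assignments come out in lexicographic order of their preorder state
    sequence and the enumeration stops after ``cap`` of them, returning a
    truncation flag.
    """
    if cap < 1:
        raise ReconstructionError("cap must be >= 1")
    tree = result.tree

    def subtree(node_id: str, state) -> Iterator[dict[str, object]]:
        children = tree.children_ids(node_id)
        if not children:
            yield {node_id: state}
            return

        def rec(i: int, acc: dict[str, object]) -> Iterator[dict[str, object]]:
            if i == len(children):
                yield dict(acc)
                return
            child = children[i]
            for child_state in _sorted_states(
                result, result.child_options(child, state)
            ):
                for sub in subtree(child, child_state):
                    acc_next = {**acc, **sub}
                    yield from rec(i + 1, acc_next)

        yield from rec(0, {node_id: state})

    def all_assignments() -> Iterator[dict[str, object]]:
        for root_state in _sorted_states(result, result.root_states()):
            yield from subtree(tree.root_id, root_state)

    out = list(itertools.islice(all_assignments(), cap + 1))
    truncated = len(out) > cap
    return out[:cap], truncated


def decompose_all_branches(
    result: ReconstructionResult, assignment: Mapping[str, object]
) -> dict[str, EventMultiset]:
    """Per-branch minimal event multisets for one MPR assignment.

    Keys are child node ids.  The assignment must be consistent with the
    per-node MPR sets; the multiset totals sum to ``total_cost``.
    """
    tree = result.tree
    for node_id in tree.preorder_ids():
        if node_id not in assignment:
            raise ReconstructionError(f"assignment misses node {node_id!r}")
        if assignment[node_id] not in result.mpr_sets[node_id]:
            raise ReconstructionError(
                f"state {assignment[node_id]} at node {node_id!r} is not in "
                "its most-parsimonious set"
            )
    branches: dict[str, EventMultiset] = {}
    for node_id in tree.preorder_ids():
        parent = tree.parent_id(node_id)
        if parent is None:
            continue
        ps, cs = assignment[parent], assignment[node_id]
        if result.character == "karyotype":
            branches[node_id] = decompose_minimal_events(ps, cs)
        else:
            dc = cs - ps
            branches[node_id] = EventMultiset(
                cma3_gains=max(0, dc), cma3_losses=max(0, -dc)
            )
    return branches


# --------------------------------------------------------------------------
# Whole-clade convenience pipeline

@dataclass
class CladeReconstruction:
    """Joint karyotype + CMA3 reconstruction with a selected scenario."""

    tree: AnnotatedTree
    karyotype: ReconstructionResult
    cma3: ReconstructionResult | None
    assignment: dict[str, KaryotypeState]
    cma3_assignment: dict[str, int] | None
    branch_events: dict[str, EventMultiset]
    combined_cost: float

    @property
    def root_state(self) -> KaryotypeState:
        return self.assignment[self.tree.root_id]

    @property
    def root_cma3(self) -> int | None:
        if self.cma3_assignment is None:
            return None
        return self.cma3_assignment[self.tree.root_id]


def reconstruct_clade(
    tree: AnnotatedTree,
    records: Sequence[KaryotypeRecord],
    slack: int = 4,
    reference: KaryotypeState | None = None,
    include_cma3: bool = True,
    clade: Sequence[str] | None = None,
) -> CladeReconstruction:
    """Run the full reconstruction used throughout the analyses.

    Reconstructs the arm-class karyotype and (optionally) the CMA3 count as
    independent characters, selects one scenario deterministically
    (reference tie-break at the root, then lexicographic), decomposes every
    branch into its minimal event multiset, and attaches everything to the
    tree for reporting.  ``clade`` restricts the analysis to the subtree
    spanned by the named leaves (pruning outgroups).
    """
    if clade is not None:
        tree = tree.extract_clade(clade)
    karyo = sankoff_reconstruct(tree, records, slack=slack)
    assignment = select_assignment(karyo, reference=reference)
    branch_events = decompose_all_branches(karyo, assignment)
    combined = karyo.total_cost

    cma3_result = None
    cma3_assignment = None
    if include_cma3:
        leaf_records = match_records_to_leaves(tree, records)
        counts = {leaf: rec.cma3_pairs for leaf, rec in leaf_records.items()}
        cma3_result = reconstruct_count_character(tree, counts)
        cma3_assignment = select_assignment(cma3_result)
        cma3_branches = decompose_all_branches(cma3_result, cma3_assignment)
        branch_events = {
            child: branch_events[child] + cma3_branches[child]
            for child in branch_events
        }
        combined = combined + cma3_result.total_cost

    tree.states = dict(assignment)
    if cma3_assignment is not None:
        tree.cma3_states = dict(cma3_assignment)
    tree.branch_events = dict(branch_events)
    return CladeReconstruction(
        tree=tree,
        karyotype=karyo,
        cma3=cma3_result,
        assignment=assignment,
        cma3_assignment=cma3_assignment,
        branch_events=branch_events,
        combined_cost=combined,
    )
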