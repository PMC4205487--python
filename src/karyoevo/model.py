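"""Karyotype states and the chromosomal rearrangement event algebra.

A karyotype is summarised as counts of homologous chromosome pairs in two
arm classes: *biarmed* (metacentric + submetacentric, written ``m-sm``) and
*uniarmed* (subtelocentric + acrocentric, written ``st-a``), optionally
augmented with the number of pairs bearing CMA3-positive (GC-rich,
NOR-associated) fluorescent signals.  Working in pair units makes every
rearrangement an integer step on a lattice:

* centric (Robertsonian) **fusion** — two uniarmed pairs join into one
  biarmed pair, ``(M, A) -> (M+1, A-2)``, lowering 2n by 2;
* **fission** — one biarmed pair falls apart into two uniarmed pairs,
  ``(M, A) -> (M-1, A+2)``, raising 2n by 2;
* **pericentric inversion** — moves the centromere, converting one pair
  between the arm classes without changing 2n;
* **CMA3 gain / loss** — adds or removes one signal-bearing pair.

The module provides formula parsing ("18m-sm+26st-a"), event application
with feasibility checks, a closed-form minimal event distance with an exact
feasibility test, its unique minimal decomposition into event counts, and a
breadth-first-search oracle over the lattice.
"""

from __future__ import annotations

import math
import re
import warnings
from collections import deque
from dataclasses import dataclass, fields
from enum import Enum
from functools import lru_cache
from typing import Iterable

__all__ = [
    "KaryotypeError",
    "FormulaError",
    "FeasibilityError",
    "UnreachableError",
    "EventKind",
    "EFFECTS",
    "KaryotypeState",
    "EventMultiset",
    "parse_karyotype_formula",
    "format_karyotype_formula",
    "apply_event",
    "event_distance",
    "decompose_minimal_events",
    "min_event_path",
]


class KaryotypeError(ValueError):
    """Base class for errors raised by the karyotype model."""


class FormulaError(KaryotypeError):
    """A karyotype formula string could not be parsed."""


class FeasibilityError(KaryotypeError):
    """A rearrangement event is not applicable to the given state."""


class UnreachableError(KaryotypeError):
    """No feasible event path connects the two states."""


class EventKind(str, Enum):
    """The six kinds of rearrangement / signal events."""

    FUSION = "fusion"
    FISSION = "fission"
    INV_M_TO_A = "inv_m_to_a"
    INV_A_TO_M = "inv_a_to_m"
    CMA3_GAIN = "cma3_gain"
    CMA3_LOSS = "cma3_loss"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Effect vectors (dM, dA, dc) in pair units.
EFFECTS: dict[EventKind, tuple[int, int, int]] = {
    EventKind.FUSION: (+1, -2, 0),
    EventKind.FISSION: (-1, +2, 0),
    EventKind.INV_M_TO_A: (-1, +1, 0),
    EventKind.INV_A_TO_M: (+1, -1, 0),
    EventKind.CMA3_GAIN: (0, 0, +1),
    EventKind.CMA3_LOSS: (0, 0, -1),
}

#: Inverse event of each kind, where one exists.
INVERSE: dict[EventKind, EventKind] = {
    EventKind.FUSION: EventKind.FISSION,
    EventKind.FISSION: EventKind.FUSION,
    EventKind.INV_M_TO_A: EventKind.INV_A_TO_M,
    EventKind.INV_A_TO_M: EventKind.INV_M_TO_A,
    EventKind.CMA3_GAIN: EventKind.CMA3_LOSS,
    EventKind.CMA3_LOSS: EventKind.CMA3_GAIN,
}


@dataclass(frozen=True)
class KaryotypeState:
    """A point in the karyotype lattice, in homologous-pair units.

    Parameters
    ----------
    biarmed_pairs:
        Number of metacentric/submetacentric (biarmed) pairs, ``M``.
    uniarmed_pairs:
        Number of subtelocentric/acrocentric (uniarmed) pairs, ``A``.
    cma3_pairs:
        Number of pairs bearing CMA3-positive signals, or ``None`` when the
        signal phenotype is not tracked.
    """

    biarmed_pairs: int
    uniarmed_pairs: int
    cma3_pairs: int | None = None

    def __post_init__(self) -> None:
        m, a, c = self.biarmed_pairs, self.uniarmed_pairs, self.cma3_pairs
        if m < 0 or a < 0:
            raise KaryotypeError(f"negative pair count in state (M={m}, A={a})")
        if c is not None:
            if c < 0:
                raise KaryotypeError(f"negative CMA3 pair count ({c})")
            if c > m + a:
                raise KaryotypeError(
                    f"CMA3 pair count {c} exceeds total pair count {m + a}"
                )

    @property
    def pair_number(self) -> int:
        """Haploid chromosome number n = M + A."""
        return self.biarmed_pairs + self.uniarmed_pairs

    @property
    def diploid_number(self) -> int:
        """Diploid chromosome number 2n (always even in pair units)."""
        return 2 * self.pair_number

    @property
    def formula(self) -> str:
        """Canonical karyotype formula, e.g. ``'16m-sm+32st-a'``."""
        return format_karyotype_formula(self)

    def sort_key(self) -> tuple[int, int, int]:
        """Deterministic (M, A, c) ordering key; absent c sorts first."""
        c = -1 if self.cma3_pairs is None else self.cma3_pairs
        return (self.biarmed_pairs, self.uniarmed_pairs, c)

    def drop_cma3(self) -> "KaryotypeState":
        """The same arm-class state with the CMA3 component removed."""
        if self.cma3_pairs is None:
            return self
        return KaryotypeState(self.biarmed_pairs, self.uniarmed_pairs)

    def __str__(self) -> str:
        s = self.formula
        if self.cma3_pairs is not None:
            s += f" [CMA3:{self.cma3_pairs}]"
        return s


@dataclass(frozen=True)
class EventMultiset:
    """Per-branch counts of each event kind.

    A *minimal* decomposition satisfies ``min(fusions, fissions) == 0``,
    ``min(inv_m_to_a, inv_a_to_m) == 0`` and
    ``min(cma3_gains, cma3_losses) == 0``; its total then equals the event
    distance between the branch endpoints.
    """

    fusions: int = 0
    fissions: int = 0
    inv_m_to_a: int = 0
    inv_a_to_m: int = 0
    cma3_gains: int = 0
    cma3_losses: int = 0

    _FIELD_BY_KIND = {
        EventKind.FUSION: "fusions",
        EventKind.FISSION: "fissions",
        EventKind.INV_M_TO_A: "inv_m_to_a",
        EventKind.INV_A_TO_M: "inv_a_to_m",
        EventKind.CMA3_GAIN: "cma3_gains",
        EventKind.CMA3_LOSS: "cma3_losses",
    }

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise KaryotypeError(f"negative event count for {f.name}")

    @classmethod
    def from_events(cls, events: Iterable[EventKind]) -> "EventMultiset":
        counts: dict[str, int] = {}
        for ev in events:
            name = cls._FIELD_BY_KIND[EventKind(ev)]
            counts[name] = counts.get(name, 0) + 1
        return cls(**counts)

    def counts(self) -> dict[EventKind, int]:
        return {k: getattr(self, f) for k, f in self._FIELD_BY_KIND.items()}

    @property
    def total(self) -> int:
        return sum(getattr(self, f.name) for f in fields(self))

    def is_minimal(self) -> bool:
        return (
            min(self.fusions, self.fissions) == 0
            and min(self.inv_m_to_a, self.inv_a_to_m) == 0
            and min(self.cma3_gains, self.cma3_losses) == 0
        )

    def __add__(self, other: "EventMultiset") -> "EventMultiset":
        return EventMultiset(
            **{
                f.name: getattr(self, f.name) + getattr(other, f.name)
                for f in fields(self)
            }
        )

    def __str__(self) -> str:
        parts = [
            f"{kind.value}:{n}" for kind, n in self.counts().items() if n > 0
        ]
        return ",".join(parts) if parts else "-"

    def describe(self) -> str:
        """Human-readable rendering, e.g. ``'2 fusions + 1 inversion (m-sm -> st-a)'``."""
        labels = {
            EventKind.FUSION: ("fusion", "fusions"),
            EventKind.FISSION: ("fission", "fissions"),
            EventKind.INV_M_TO_A: (
                "inversion (m-sm -> st-a)",
                "inversions (m-sm -> st-a)",
            ),
            EventKind.INV_A_TO_M: (
                "inversion (st-a -> m-sm)",
                "inversions (st-a -> m-sm)",
            ),
            EventKind.CMA3_GAIN: ("CMA3 gain", "CMA3 gains"),
            EventKind.CMA3_LOSS: ("CMA3 loss", "CMA3 losses"),
        }
        parts = [
            f"{n} {labels[kind][0 if n == 1 else 1]}"
            for kind, n in self.counts().items()
            if n > 0
        ]
        return " + ".join(parts) if parts else "no events"


# --------------------------------------------------------------------------
# Formula parsing

_TERM_RE = re.compile(r"^(\d+)\s*([A-Za-z][A-Za-z\-]*)$")
_BIARMED_TOKENS = frozenset({"m", "sm", "m-sm"})
_UNIARMED_TOKENS = frozenset({"st", "a", "st-a", "t"})


def parse_karyotype_formula(
    text: str, *, cma3_pairs: int | None = None, lenient: bool = False
) -> KaryotypeState:
    """Parse a karyotype formula such as ``'18m-sm+26st-a'`` or ``'14sm+36st-a'``.

    The formula is a ``+``-separated list of ``<count><category>`` terms in
    which counts are *diploid* chromosome counts.  Category tokens (case
    insensitive) ``m``, ``sm`` and ``m-sm`` are pooled as biarmed;
    ``st``, ``a``, ``st-a`` and ``t`` as uniarmed.

    Parameters
    ----------
    text:
        The formula string.
    cma3_pairs:
        Optional CMA3 signal pair count to attach to the returned state.
    lenient:
        Chromosome counts per arm class must be even (homologues pair up in
        a diploid complement); odd totals raise :class:`FormulaError` unless
        ``lenient`` is true, in which case they are floored to whole pairs
        with a warning.

    Returns
    -------
    KaryotypeState
        The parsed state in pair units.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError(f"empty or non-string karyotype formula: {text!r}")
    biarmed = 0
    uniarmed = 0
    for raw_term in text.split("+"):
        term = raw_term.strip()
        match = _TERM_RE.match(term)
        if match is None:
            raise FormulaError(
                f"unparseable term {raw_term.strip()!r} in formula {text!r}"
            )
        count = int(match.group(1))
        category = match.group(2).lower()
        if category in _BIARMED_TOKENS:
            biarmed += count
        elif category in _UNIARMED_TOKENS:
            uniarmed += count
        else:
            raise FormulaError(
                f"unrecognized chromosome category {category!r} in formula {text!r}"
            )
    for label, total in (("m-sm", biarmed), ("st-a", uniarmed)):
        if total % 2 != 0:
            if lenient:
                warnings.warn(
                    f"odd {label} chromosome count {total} in {text!r}; "
                    "flooring to whole pairs",
                    stacklevel=2,
                )
            else:
                raise FormulaError(
                    f"odd {label} chromosome count {total} in formula {text!r}: "
                    "chromosomes in a diploid complement must pair"
                )
    return KaryotypeState(biarmed // 2, uniarmed // 2, cma3_pairs)


def format_karyotype_formula(state: KaryotypeState) -> str:
    """Canonical formula ``'<2M>m-sm+<2A>st-a'`` for a state."""
    return f"{2 * state.biarmed_pairs}m-sm+{2 * state.uniarmed_pairs}st-a"


# --------------------------------------------------------------------------
# Event application

def apply_event(state: KaryotypeState, event: EventKind) -> KaryotypeState:
    """Apply one event to a state, returning the new state.

    Raises :class:`FeasibilityError` when the event's precondition fails:
    fusion needs two uniarmed pairs, fission and m->a inversion need a
    biarmed pair, a->m inversion needs a uniarmed pair, CMA3 loss needs a
    signal-bearing pair, and a CMA3 gain or a fusion must not push the
    signal count above the total pair count.
    """
    event = EventKind(event)
    dm, da, dc = EFFECTS[event]
    if dc != 0 and state.cma3_pairs is None:
        raise FeasibilityError(
            f"{event.value} requires a state tracking CMA3 pairs"
        )
    m = state.biarmed_pairs + dm
    a = state.uniarmed_pairs + da
    c = None if state.cma3_pairs is None else state.cma3_pairs + dc
    if m < 0 or a < 0 or (c is not None and (c < 0 or c > m + a)):
        raise FeasibilityError(
            f"{event.value} infeasible from {state}: "
            + _precondition_text(event)
        )
    return KaryotypeState(m, a, c)


def _precondition_text(event: EventKind) -> str:
    return {
        EventKind.FUSION: "requires at least 2 uniarmed pairs (A >= 2)",
        EventKind.FISSION: "requires a biarmed pair (M >= 1)",
        EventKind.INV_M_TO_A: "requires a biarmed pair (M >= 1)",
        EventKind.INV_A_TO_M: "requires a uniarmed pair (A >= 1)",
        EventKind.CMA3_GAIN: "requires a signal-free pair (c < M + A)",
        EventKind.CMA3_LOSS: "requires a signal-bearing pair (c >= 1)",
    }[event]


def is_feasible(state: KaryotypeState, event: EventKind) -> bool:
    """Whether ``apply_event(state, event)`` would succeed."""
    try:
        apply_event(state, event)
    except FeasibilityError:
        return False
    return True


# --------------------------------------------------------------------------
# Minimal event distance

def _minimal_counts(
    m1: int, a1: int, m2: int, a2: int
) -> tuple[int, int, int, int]:
    """Forced minimal (fusions, fissions, inv_m_to_a, inv_a_to_m) counts.

    Fusions/fissions are the only events changing the pair number
    N = M + A, so any path has (fissions - fusions) = dN; inversions then
    absorb the residual arm-class change (inv_a_to_m - inv_m_to_a) =
    dM + dN.  Minimality forces one count in each opposing pair to zero.
    """
    dn = (m2 + a2) - (m1 + a1)
    dk = (m2 - m1) + dn
    return (max(0, -dn), max(0, dn), max(0, -dk), max(0, dk))


@lru_cache(maxsize=None)
def _multiset_feasible(
    m1: int, a1: int, x: int, y: int, u: int, v: int
) -> bool:
    """Exact test: can the multiset be ordered into a feasible path from (m1, a1)?

    At most one of (x, y) and one of (u, v) is nonzero, so a candidate path
    is a monotone walk on an (i, j) grid: i applications of the
    fusion/fission kind interleaved with j inversions.  Dynamic-programming
    reachability over the grid decides feasibility exactly.
    """
    if x and y or u and v:
        raise KaryotypeError("multiset is not minimal")
    fkind = EventKind.FUSION if x else EventKind.FISSION
    ikind = EventKind.INV_M_TO_A if u else EventKind.INV_A_TO_M
    f, g = x + y, u + v
    fdm, fda, _ = EFFECTS[fkind]
    idm, ida, _ = EFFECTS[ikind]

    def state_at(i: int, j: int) -> tuple[int, int]:
        return (m1 + i * fdm + j * idm, a1 + i * fda + j * ida)

    def ok(m: int, a: int) -> bool:
        return m >= 0 and a >= 0

    reach = [[False] * (g + 1) for _ in range(f + 1)]
    reach[0][0] = ok(m1, a1)
    for i in range(f + 1):
        for j in range(g + 1):
            if not reach[i][j]:
                continue
            if i < f and ok(*state_at(i + 1, j)):
                reach[i + 1][j] = True
            if j < g and ok(*state_at(i, j + 1)):
                reach[i][j + 1] = True
    return reach[f][g]


@lru_cache(maxsize=None)
def _ma_distance(m1: int, a1: int, m2: int, a2: int) -> float:
    """Minimal event count between arm-class states (m1, a1) and (m2, a2).

    Closed form |dN| + |dM + dN| whenever its forced multiset can be ordered
    feasibly; otherwise falls back to breadth-first search.  ``math.inf`` is
    returned for the single unreachable case (the empty karyotype (0, 0) is
    an isolated lattice point).
    """
    x, y, u, v = _minimal_counts(m1, a1, m2, a2)
    closed = x + y + u + v
    if closed == 0:
        return 0
    if _multiset_feasible(m1, a1, x, y, u, v):
        return closed
    path = _ma_bfs(m1, a1, m2, a2)
    return math.inf if path is None else len(path)


_MA_EVENTS = (
    EventKind.FUSION,
    EventKind.FISSION,
    EventKind.INV_M_TO_A,
    EventKind.INV_A_TO_M,
)


def _ma_bfs(
    m1: int,
    a1: int,
    m2: int,
    a2: int,
    m_max: int | None = None,
    a_max: int | None = None,
) -> list[EventKind] | None:
    """Shortest feasible event path on the (M, A) lattice, or None."""
    if m_max is None:
        m_max = m1 + m2 + a1 + a2 + 2
    if a_max is None:
        a_max = 2 * (m1 + a1 + m2 + a2) + 4
    start, goal = (m1, a1), (m2, a2)
    if start == goal:
        return []
    prev: dict[tuple[int, int], tuple[tuple[int, int], EventKind]] = {}
    seen = {start}
    queue: deque[tuple[int, int]] = deque([start])
    while queue:
        m, a = queue.popleft()
        for ev in _MA_EVENTS:
            dm, da, _ = EFFECTS[ev]
            nm, na = m + dm, a + da
            if nm < 0 or na < 0 or nm > m_max or na > a_max:
                continue
            nxt = (nm, na)
            if nxt in seen:
                continue
            seen.add(nxt)
            prev[nxt] = ((m, a), ev)
            if nxt == goal:
                path: list[EventKind] = []
                cur = nxt
                while cur != start:
                    cur, ev2 = prev[cur]
                    path.append(ev2)
                path.reverse()
                return path
            queue.append(nxt)
    return None


def event_distance(s1: KaryotypeState, s2: KaryotypeState) -> float:
    """Minimum number of events transforming ``s1`` into ``s2``.

    The CMA3 component contributes ``|dc|`` when both states track it;
    states with and without a CMA3 component are otherwise compared on the
    arm-class lattice alone.  The distance is symmetric and satisfies the
    triangle inequality.  ``math.inf`` marks the unreachable empty-karyotype
    corner case.
    """
    d = _ma_distance(
        s1.biarmed_pairs, s1.uniarmed_pairs, s2.biarmed_pairs, s2.uniarmed_pairs
    )
    if s1.cma3_pairs is not None and s2.cma3_pairs is not None:
        d += abs(s2.cma3_pairs - s1.cma3_pairs)
    return d


def decompose_minimal_events(
    s1: KaryotypeState, s2: KaryotypeState
) -> EventMultiset:
    """The unique minimal event multiset transforming ``s1`` into ``s2``.

    When the forced minimal multiset admits a feasible ordering (the
    generic case) it is returned directly; at infeasible lattice corners the
    multiset of a shortest BFS path is returned instead, so that ``total``
    always equals :func:`event_distance`.
    """
    x, y, u, v = _minimal_counts(
        s1.biarmed_pairs, s1.uniarmed_pairs, s2.biarmed_pairs, s2.uniarmed_pairs
    )
    gains = losses = 0
    if s1.cma3_pairs is not None and s2.cma3_pairs is not None:
        dc = s2.cma3_pairs - s1.cma3_pairs
        gains, losses = max(0, dc), max(0, -dc)
    if (x + y + u + v) == 0 or _multiset_feasible(
        s1.biarmed_pairs, s1.uniarmed_pairs, x, y, u, v
    ):
        return EventMultiset(x, y, u, v, gains, losses)
    path = _ma_bfs(
        s1.biarmed_pairs, s1.uniarmed_pairs, s2.biarmed_pairs, s2.uniarmed_pairs
    )
    if path is None:
        raise UnreachableError(f"no feasible event path from {s1} to {s2}")
    return EventMultiset.from_events(path) + EventMultiset(
        cma3_gains=gains, cma3_losses=losses
    )


def min_event_path(
    s1: KaryotypeState,
    s2: KaryotypeState,
    bounds: tuple[int, int] | None = None,
) -> list[EventKind]:
    """Brute-force oracle: a shortest feasible event sequence from ``s1`` to ``s2``.

    Breadth-first search over the bounded lattice; every intermediate state
    satisfies the :func:`apply_event` preconditions.  ``bounds`` is
    ``(m_max, a_max)``; by default generous bounds derived from the
    endpoints are used so that no unconstrained geodesic is clipped.  The
    CMA3 component, when tracked by both endpoints, is appended as the
    required number of gain or loss events (they commute with everything).

    Raises
    ------
    UnreachableError
        If the target cannot be reached within the bounds.
    """
    m_max = a_max = None
    if bounds is not None:
        m_max, a_max = bounds
        for s in (s1, s2):
            if s.biarmed_pairs > m_max or s.uniarmed_pairs > a_max:
                raise KaryotypeError(f"state {s} outside bounds {bounds}")
    track_cma3 = s1.cma3_pairs is not None and s2.cma3_pairs is not None
    if not track_cma3:
        path = _ma_bfs(
            s1.biarmed_pairs,
            s1.uniarmed_pairs,
            s2.biarmed_pairs,
            s2.uniarmed_pairs,
            m_max,
            a_max,
        )
        if path is None:
            raise UnreachableError(
                f"no feasible event path from {s1} to {s2} within bounds"
            )
        return path
    # Full-state search when the CMA3 component is tracked: signal events
    # interact with arm events only through the c <= M + A invariant, which
    # apply_event enforces exactly.
    if m_max is None:
        m_max = s1.pair_number + s2.pair_number + 2
        a_max = 2 * (s1.pair_number + s2.pair_number) + 4
    if s1 == s2:
        return []
    prev: dict[KaryotypeState, tuple[KaryotypeState, EventKind]] = {}
    seen = {s1}
    queue: deque[KaryotypeState] = deque([s1])
    while queue:
        cur = queue.popleft()
        for ev in EventKind:
            try:
                nxt = apply_event(cur, ev)
            except FeasibilityError:
                continue
            if nxt.biarmed_pairs > m_max or nxt.uniarmed_pairs > a_max:
                continue
            if nxt in seen:
                continue
            seen.add(nxt)
            prev[nxt] = (cur, ev)
            if nxt == s2:
                path = []
                node = nxt
                while node != s1:
                    node, ev2 = prev[node]
                    path.append(ev2)
                path.reverse()
                return path
            queue.append(nxt)
    raise UnreachableError(
        f"no feasible event path from {s1} to {s2} within bounds"
    )
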