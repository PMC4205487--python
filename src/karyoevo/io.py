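"""Readers and writers: Newick trees, karyotype tables, report tables.

Karyotype tables are tab-separated text with a header row (a comma dialect
is available behind ``sep=","``), mirroring the layout of published
comparative-cytogenetics tables: one row per species with its diploid
number, karyotype formula and CMA3 signal count.  Trees are Newick;
ancestral-state annotations are written as ``[&key=value]`` comment blocks
so that third-party tree viewers still load the files.

The module also exposes the packaged study fixtures: the karyotype table of
the five Nannacara / Ivanacara / Cleithracara dwarf cichlids and the rooted
ingroup topology ``((((anomala,aureocephalus),taenia),adoketa),maronii)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Sequence

import dendropy
import pandas as pd

from .model import (
    EventMultiset,
    FormulaError,
    KaryotypeError,
    KaryotypeState,
    parse_karyotype_formula,
)

__all__ = [
    "KaryotypeRecord",
    "AnnotatedTree",
    "TableFormatError",
    "TreeFormatError",
    "read_karyotype_table",
    "write_karyotype_table",
    "read_newick",
    "write_annotated_newick",
    "write_report_table",
    "match_records_to_leaves",
    "fixture_karyotype_table_path",
    "fixture_tree_path",
    "load_fixture_records",
    "load_fixture_tree",
    "ANCESTRAL_CICHLID_KARYOTYPE",
]

#: Ancestral cichlid karyotype, 48 uniarmed chromosomes (48st-a): the
#: outgroup context used to orient the root of the ingroup reconstruction.
ANCESTRAL_CICHLID_KARYOTYPE = KaryotypeState(0, 24)


class TableFormatError(KaryotypeError):
    """A karyotype table failed validation."""


class TreeFormatError(KaryotypeError):
    """A Newick tree failed to parse or validate."""


@dataclass(frozen=True)
class KaryotypeRecord:
    """One species row of a karyotype table."""

    species: str
    diploid_number: int
    formula: str
    cma3_pairs: int

    def state(self, *, include_cma3: bool = False) -> KaryotypeState:
        """The record's karyotype as a lattice state."""
        return parse_karyotype_formula(
            self.formula, cma3_pairs=self.cma3_pairs if include_cma3 else None
        )


# --------------------------------------------------------------------------
# Karyotype tables

_COLUMN_ALIASES = {
    "species": "species",
    "taxon": "species",
    "label": "species",
    "2n": "2n",
    "diploid_number": "2n",
    "karyotype": "karyotype",
    "formula": "karyotype",
    "cma3": "cma3",
    "cma3_signals": "cma3",
    "cma3_pairs": "cma3",
}

_CMA3_CELL_RE = re.compile(r"^\s*(\d+)")


def _parse_cma3_cell(value: object, row_label: str) -> int:
    """CMA3 cells may be bare integers or phrases like ``'3 m-sm pair'``."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if float(value) != int(value):
            raise TableFormatError(
                f"non-integer CMA3 count {value!r} for {row_label}"
            )
        return int(value)
    match = _CMA3_CELL_RE.match(str(value))
    if match is None:
        raise TableFormatError(
            f"cannot read CMA3 signal count from {value!r} for {row_label}"
        )
    return int(match.group(1))


def read_karyotype_table(
    path: str | Path | IO[str], sep: str = "\t"
) -> list[KaryotypeRecord]:
    """Read and validate a karyotype table.

    Expected columns (order free, case-insensitive, common aliases
    accepted): ``species``, ``2n``, ``karyotype``, ``cma3``.  Every row is
    cross-checked: the formula must parse and its chromosome total must
    equal the stated diploid number; species labels must be unique.
    """
    frame = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    renames: dict[str, str] = {}
    for col in frame.columns:
        key = col.strip().lower()
        if key in _COLUMN_ALIASES:
            renames[col] = _COLUMN_ALIASES[key]
    frame = frame.rename(columns=renames)
    missing = {"species", "2n", "karyotype", "cma3"} - set(frame.columns)
    if missing:
        raise TableFormatError(
            f"karyotype table is missing column(s): {', '.join(sorted(missing))}"
        )
    records: list[KaryotypeRecord] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        species = str(row["species"]).strip()
        if species in seen:
            raise TableFormatError(f"duplicate species {species!r} (row {idx + 1})")
        seen.add(species)
        try:
            two_n = int(str(row["2n"]).strip())
        except ValueError as exc:
            raise TableFormatError(
                f"non-integer 2n {row['2n']!r} for {species!r} (row {idx + 1})"
            ) from exc
        formula = str(row["karyotype"]).strip()
        try:
            state = parse_karyotype_formula(formula)
        except FormulaError as exc:
            raise TableFormatError(
                f"bad karyotype formula for {species!r} (row {idx + 1}): {exc}"
            ) from exc
        if state.diploid_number != two_n:
            raise TableFormatError(
                f"2n mismatch for {species!r} (row {idx + 1}): formula "
                f"{formula!r} totals {state.diploid_number}, table says {two_n}"
            )
        cma3 = _parse_cma3_cell(row["cma3"], f"{species!r} (row {idx + 1})")
        if cma3 > state.pair_number:
            raise TableFormatError(
                f"CMA3 pair count {cma3} exceeds chromosome pairs "
                f"{state.pair_number} for {species!r} (row {idx + 1})"
            )
        records.append(KaryotypeRecord(species, two_n, formula, cma3))
    return records


def write_karyotype_table(
    records: Sequence[KaryotypeRecord], path: str | Path, sep: str = "\t"
) -> None:
    """Write records in the same dialect :func:`read_karyotype_table` reads."""
    frame = pd.DataFrame(
        {
            "species": [r.species for r in records],
            "2n": [r.diploid_number for r in records],
            "karyotype": [r.formula for r in records],
            "cma3_signals": [r.cma3_pairs for r in records],
        }
    )
    frame.to_csv(path, sep=sep, index=False)


# --------------------------------------------------------------------------
# Trees

class AnnotatedTree:
    """A rooted tree with stable node identifiers and optional annotations.

    Node identifiers are assigned in preorder: leaves keep their taxon
    labels, internal nodes are named ``N1, N2, ...`` (the root is ``N1`` on
    a fully internal root).  Per-node states and per-branch event multisets
    can be attached for reporting.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.states: dict[str, KaryotypeState] = {}
        self.cma3_states: dict[str, int] = {}
        self.branch_events: dict[str, EventMultiset] = {}
        self._index()

    def _index(self) -> None:
        self._id_to_node: dict[str, dendropy.Node] = {}
        self.node_ids: list[str] = []
        counter = 0
        labels_seen: set[str] = set()
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
                if not label:
                    raise TreeFormatError("tree has an unlabeled leaf")
                if label in labels_seen:
                    raise TreeFormatError(f"duplicate leaf label {label!r}")
                labels_seen.add(label)
            else:
                counter += 1
                label = f"N{counter}"
            node.karyoevo_id = label
            self._id_to_node[label] = node
            self.node_ids.append(label)

    # -- structure queries -------------------------------------------------
    @property
    def root_id(self) -> str:
        return self.tree.seed_node.karyoevo_id

    @property
    def leaf_labels(self) -> list[str]:
        return [
            nd.karyoevo_id for nd in self.tree.leaf_node_iter()
        ]

    def node(self, node_id: str) -> dendropy.Node:
        return self._id_to_node[node_id]

    def parent_id(self, node_id: str) -> str | None:
        parent = self._id_to_node[node_id].parent_node
        return None if parent is None else parent.karyoevo_id

    def children_ids(self, node_id: str) -> list[str]:
        return [c.karyoevo_id for c in self._id_to_node[node_id].child_nodes()]

    def is_leaf(self, node_id: str) -> bool:
        return self._id_to_node[node_id].is_leaf()

    def branch_length(self, node_id: str) -> float | None:
        return self._id_to_node[node_id].edge.length

    def has_branch_lengths(self) -> bool:
        return all(
            nd.edge.length is not None
            for nd in self.tree.preorder_node_iter()
            if nd.parent_node is not None
        )

    def preorder_ids(self) -> list[str]:
        return list(self.node_ids)

    # -- derived trees -----------------------------------------------------
    def extract_clade(self, leaf_labels: Sequence[str]) -> "AnnotatedTree":
        """Subtree spanned by the MRCA of the given leaves (outgroup pruning)."""
        taxa = [
            t
            for t in self.tree.taxon_namespace
            if t.label in set(leaf_labels)
        ]
        if len(taxa) != len(set(leaf_labels)):
            known = {t.label for t in self.tree.taxon_namespace}
            missing = sorted(set(leaf_labels) - known)
            raise TreeFormatError(f"leaf label(s) not in tree: {missing}")
        mrca = self.tree.mrca(taxa=taxa)
        clone = dendropy.Tree(
            seed_node=mrca.extract_subtree(), taxon_namespace=dendropy.TaxonNamespace()
        )
        clone.is_rooted = True
        # extract_subtree leaves taxa unassigned; rebuild from labels
        for leaf in clone.leaf_node_iter():
            if leaf.taxon is None and leaf.label:
                leaf.taxon = clone.taxon_namespace.new_taxon(leaf.label)
                leaf.label = None
        clone.update_taxon_namespace()
        return AnnotatedTree(clone)

    # -- newick ------------------------------------------------------------
    def as_newick(self, annotations: bool = False) -> str:
        if annotations:
            self._attach_annotations()
        return self.tree.as_string(
            schema="newick",
            suppress_annotations=not annotations,
            suppress_rooting=True,
        )

    def _attach_annotations(self) -> None:
        for node in self.tree.preorder_node_iter():
            node.annotations.clear()
            node_id = node.karyoevo_id
            state = self.states.get(node_id)
            if state is not None:
                node.annotations.add_new("karyotype", state.formula)
                node.annotations.add_new("2n", str(state.diploid_number))
            if node_id in self.cma3_states:
                node.annotations.add_new("cma3", str(self.cma3_states[node_id]))
            events = self.branch_events.get(node_id)
            if events is not None and events.total:
                node.annotations.add_new("events", str(events))


def read_newick(path: str | Path | IO[str]) -> AnnotatedTree:
    """Read a single rooted Newick tree.

    Annotation/comment blocks are tolerated and ignored.  Malformed input
    raises :class:`TreeFormatError` carrying the underlying parser message
    (which names the line and column); duplicate or empty leaf labels are
    rejected.
    """
    try:
        if hasattr(path, "read"):
            tree = dendropy.Tree.get(
                file=path, schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                path=str(path), schema="newick", preserve_underscores=True
            )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise TreeFormatError(f"cannot parse Newick tree: {exc}") from exc
    tree.is_rooted = True
    return AnnotatedTree(tree)


def write_annotated_newick(tree: AnnotatedTree, path: str | Path) -> None:
    """Write the tree, embedding any node states as ``[&key=value]`` comments.

    The output remains loadable by :func:`read_newick` (comments are
    ignored on reading), so topology round-trips exactly.
    """
    annotated = bool(tree.states or tree.cma3_states or tree.branch_events)
    Path(path).write_text(tree.as_newick(annotations=annotated))


def match_records_to_leaves(
    tree: AnnotatedTree, records: Sequence[KaryotypeRecord]
) -> dict[str, KaryotypeRecord]:
    """Map each leaf label to its karyotype record.

    Exact label matches are preferred; otherwise a leaf label matches a
    record whose species name ends with it (so the leaf ``anomala`` picks up
    the row ``Nannacara anomala``).  Ambiguous or missing matches raise.
    """
    by_label: dict[str, KaryotypeRecord] = {r.species: r for r in records}
    mapping: dict[str, KaryotypeRecord] = {}
    for leaf in tree.leaf_labels:
        if leaf in by_label:
            mapping[leaf] = by_label[leaf]
            continue
        hits = [
            r
            for r in records
            if r.species.lower().split()[-1] == leaf.lower()
            or r.species.lower().endswith(leaf.lower())
        ]
        if len(hits) == 1:
            mapping[leaf] = hits[0]
        elif not hits:
            raise TableFormatError(
                f"no karyotype record matches leaf {leaf!r}"
            )
        else:
            raise TableFormatError(
                f"leaf {leaf!r} matches multiple records: "
                f"{[r.species for r in hits]}"
            )
    return mapping


# --------------------------------------------------------------------------
# Report tables

def write_report_table(result, path: str | Path, sep: str = "\t") -> None:
    """Write a reconstruction result as a flat node + branch table.

    One row per node (most-parsimonious state set and the selected state)
    followed by one row per branch (its minimal event multiset, ``-`` when
    empty), in preorder traversal order so output is deterministic.
    ``result`` is a :class:`karyoevo.reconstruct.CladeReconstruction`.
    """
    tree = result.tree
    rows: list[dict[str, object]] = []
    for node_id in tree.preorder_ids():
        state = result.assignment[node_id]
        mpr = result.karyotype.mpr_sets[node_id]
        row: dict[str, object] = {
            "row_type": "node",
            "id": node_id,
            "parent": tree.parent_id(node_id) or "-",
            "mpr_states": ";".join(s.formula for s in mpr),
            "karyotype": state.formula,
            "2n": state.diploid_number,
            "events": "-",
        }
        if result.cma3_assignment is not None:
            row["cma3"] = result.cma3_assignment[node_id]
            row["cma3_mpr"] = ";".join(
                str(c) for c in result.cma3.mpr_sets[node_id]
            )
        rows.append(row)
    for node_id in tree.preorder_ids():
        parent = tree.parent_id(node_id)
        if parent is None:
            continue
        events = result.branch_events.get(node_id, EventMultiset())
        row = {
            "row_type": "branch",
            "id": node_id,
            "parent": parent,
            "mpr_states": "-",
            "karyotype": "-",
            "2n": "-",
            "events": str(events),
        }
        if result.cma3_assignment is not None:
            row["cma3"] = "-"
            row["cma3_mpr"] = "-"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# --------------------------------------------------------------------------
# Packaged fixtures

def fixture_karyotype_table_path() -> Path:
    """Path to the packaged five-species dwarf cichlid karyotype table."""
    return Path(
        resources.files("karyoevo").joinpath(
            "data/dwarf_cichlid_karyotypes.tsv"
        )
    )


def fixture_tree_path() -> Path:
    """Path to the packaged rooted ingroup topology (Newick)."""
    return Path(resources.files("karyoevo").joinpath("data/nic_clade.nwk"))


def load_fixture_records() -> list[KaryotypeRecord]:
    """The packaged karyotype table, read and validated."""
    return read_karyotype_table(fixture_karyotype_table_path())


def load_fixture_tree() -> AnnotatedTree:
    """The packaged rooted ingroup topology."""
    return read_newick(fixture_tree_path())
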