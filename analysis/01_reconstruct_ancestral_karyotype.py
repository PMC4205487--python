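"""Reconstruct the ancestral karyotype of the dwarf cichlid clade.

Runs Sankoff parsimony with the rearrangement event-distance cost on the
packaged inputs — the rooted five-species topology
((((anomala,aureocephalus),taenia),adoketa),maronii) and the species
karyotype table — and writes the node/branch report, the annotated tree and
the event scenario under results/.

Run from the repository root:  python analysis/01_reconstruct_ancestral_karyotype.py
"""

from pathlib import Path

from karyoevo import (
    ANCESTRAL_CICHLID_KARYOTYPE,
    load_fixture_records,
    load_fixture_tree,
    reconstruct_clade,
    write_annotated_newick,
    write_report_table,
)
from karyoevo.cli import scenario_text

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    tree = load_fixture_tree()
    records = load_fixture_records()
    result = reconstruct_clade(
        tree, records, reference=ANCESTRAL_CICHLID_KARYOTYPE
    )

    write_report_table(result, OUT / "ancestral_reconstruction.tsv")
    write_annotated_newick(result.tree, OUT / "ancestral_reconstruction.nwk")
    text = scenario_text(result)
    (OUT / "scenario.txt").write_text(text)

    root = result.root_state
    print(
        f"Root ancestral karyotype: 2n={root.diploid_number} ({root.formula}); "
        f"root CMA3 signal pairs: {result.root_cma3}"
    )
    print(
        f"Parsimony cost: {result.karyotype.total_cost} rearrangements "
        f"+ {result.cma3.total_cost} CMA3 events"
    )
    ties = [s.formula for s in result.karyotype.root_states()]
    if len(ties) > 1:
        print(
            f"Root states tied at minimal cost: {ties}; selected by proximity "
            f"to the ancestral cichlid karyotype "
            f"({ANCESTRAL_CICHLID_KARYOTYPE.formula})"
        )
    print()
    print(text)
    print(f"wrote report, tree and scenario to {OUT}")


if __name__ == "__main__":
    main()
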