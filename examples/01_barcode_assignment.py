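"""Two-step barcode assignment of query COI sequences to genera.

Builds a synthetic reference study (3 genera x 4 species, within-genus K2P
around 1%, between-genus around 10%), then attributes every query first by
the 2% K2P threshold and, where that fails, by the sister-relationship rule
on a neighbor-joining placement tree.
"""

import bathyphy as bp

fixture = bp.make_reference_fixture(
    n_genera=3, species_per_genus=4, within_d=0.01, between_d=0.10, seed=101
)

print("reference set:", len(fixture.refs), "species in", len(fixture.refs.genera), "genera")
print("queries:", fixture.queries.n_taxa, "\n")

for threshold in (0.02, 0.005):
    results = bp.run_assignment(
        fixture.queries, fixture.refs, fixture.ref_alignment, threshold=threshold
    )
    correct = sum(r.genus == fixture.truth[r.query] for r in results)
    print(f"--- threshold {threshold:.1%} ---")
    print(f"{'query':<10}{'closest ref':<16}{'K2P':>8}  {'genus':<10}{'rule'}")
    for r in results:
        dist = "" if r.min_distance is None else f"{r.min_distance:.4f}"
        print(f"{r.query:<10}{(r.matched_taxon or '-'):<16}{dist:>8}  {r.genus or '-':<10}{r.rule}")
    print(f"correct genus for {correct}/{len(results)} queries\n")

print(
    "At 2% every query sits within the threshold of its conspecific reference\n"
    "and inherits that genus directly. At a deliberately tightened 0.5% some\n"
    "queries exceed the threshold; those fall through to the sister rule,\n"
    "which still recovers the right genus from the placement tree."
)
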