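"""Molecular assignation of query sequences to species/ESUs and genera.

Two-step barcoding procedure:

1. *Threshold step* — compute the K2P distance from the query to every
   reference sequence; if the minimum is at or below the threshold (default
   2%, boundary inclusive), the query is attributed to the closest reference
   species/ESU and inherits its genus.
2. *Sister step* — queries left unassigned are placed in a phylogenetic tree
   containing the reference taxa (an externally inferred tree, or a
   neighbor-joining tree built on demand) and attributed to a genus when
   their sister group — a reference species or clade of species — is
   genus-homogeneous.

Ties and saturated distances are reported, never silently resolved; queries
with no molecular signal can be passed through as morphology-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .alignment import MultiLocusAlignment
from .distances import (
    k2p_distance,
    nj_tree,
    pairwise_matrix,
)
from .errors import (
    NoComparableSitesError,
    NoSisterError,
    SaturationError,
    UnknownTaxonError,
)
from .tables import ReferenceTable
from .trees import PhyloTree, sister_group

log = logging.getLogger(__name__)

#: Distances closer than this are treated as tied for the minimum.
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of assigning one query sequence."""

    query: str
    matched_taxon: str | None = None
    min_distance: float | None = None
    n_sites: int | None = None
    genus: str | None = None
    rule: str = "unresolved"  # threshold | sister | unresolved | morphology_only
    notes: str = ""


def _distances_to_refs(
    query_seq: str,
    refs: ReferenceTable,
    ref_aln: MultiLocusAlignment,
    min_sites: int,
) -> tuple[dict[str, tuple[float, int]], list[str]]:
    """K2P to every reference; returns (defined distances, skipped-pair notes)."""
    defined: dict[str, tuple[float, int]] = {}
    skipped: list[str] = []
    seqs = ref_aln.unmasked_sequences()
    for record in refs:
        if record.taxon not in seqs:
            continue
        try:
            d, n = k2p_distance(query_seq, seqs[record.taxon])
        except NoComparableSitesError:
            skipped.append(f"{record.taxon}:no-overlap")
            continue
        except SaturationError:
            skipped.append(f"{record.taxon}:saturated")
            continue
        if n < min_sites:
            skipped.append(f"{record.taxon}:overlap<{min_sites}")
            continue
        defined[record.taxon] = (d, n)
    return defined, skipped


def assign_by_threshold(
    query: str,
    query_seq: str,
    refs: ReferenceTable,
    ref_aln: MultiLocusAlignment,
    threshold: float = 0.02,
    min_sites: int = 100,
) -> AssignmentResult:
    """Attribute a query to the closest reference species/ESU if within threshold.

    Co-minimal references (within 1e-12 of the minimum) are all reported; the
    genus is copied only when they agree on one genus. Saturated pairs and
    pairs with fewer than `min_sites` comparable sites never support an
    attribution.
    """
    defined, skipped = _distances_to_refs(query_seq, refs, ref_aln, min_sites)
    note = f"skipped={';'.join(skipped)}" if skipped else ""
    if not defined:
        return AssignmentResult(
            query, rule="morphology_only",
            notes=(note + " no usable K2P distance to any reference").strip(),
        )
    dmin = min(d for d, _ in defined.values())
    comins = sorted(t for t, (d, _) in defined.items() if d - dmin <= _TIE_TOL)
    n_sites = defined[comins[0]][1]
    if dmin > threshold:
        return AssignmentResult(
            query, min_distance=dmin, n_sites=n_sites,
            notes=(note + f" min K2P {dmin:.4f} > threshold {threshold:g}").strip(),
        )
    genera = sorted({refs.genus_of(t) for t in comins})
    if len(genera) > 1:
        return AssignmentResult(
            query, matched_taxon=",".join(comins), min_distance=dmin,
            n_sites=n_sites, rule="unresolved",
            notes=(note + f" co-minimal references span genera {genera}").strip(),
        )
    return AssignmentResult(
        query,
        matched_taxon=",".join(comins),
        min_distance=dmin,
        n_sites=n_sites,
        genus=genera[0],
        rule="threshold",
        notes=(note + (f" tie among {comins}" if len(comins) > 1 else "")).strip(),
    )


def assign_by_sister(
    query: str,
    placement_tree: PhyloTree,
    refs: ReferenceTable,
) -> AssignmentResult:
    """Attribute a genus from the sister relationship in a placement tree.

    The sister group of the query is inspected; if it holds no reference
    taxon the search walks one level rootward at a time (bounded by the
    root). At the first level containing references, the genus is assigned
    iff those references are genus-homogeneous.
    """
    ref_taxa = set(refs.taxa)
    target: set[str] = {query}
    levels = 0
    while True:
        try:
            sisters = sister_group(placement_tree, target)
        except NoSisterError:
            return AssignmentResult(
                query, rule="unresolved",
                notes="sister search reached the root without meeting a reference",
            )
        informative = sorted(sisters & ref_taxa)
        if informative:
            genera = sorted({refs.genus_of(t) for t in informative})
            walk = f" after {levels} rootward step(s)" if levels else ""
            if len(genera) == 1:
                return AssignmentResult(
                    query, genus=genera[0], rule="sister",
                    notes=f"sister group {informative}{walk}",
                )
            return AssignmentResult(
                query, rule="unresolved",
                notes=f"sister group {informative} spans genera {genera}{walk}",
            )
        target = target | set(sisters)
        levels += 1


def run_assignment(
    queries: MultiLocusAlignment,
    refs: ReferenceTable,
    ref_aln: MultiLocusAlignment,
    threshold: float = 0.02,
    placement: PhyloTree | None = None,
    min_sites: int = 100,
    morphology_only: Iterable[str] = (),
) -> list[AssignmentResult]:
    """Full two-step assignation for a set of query sequences.

    Queries named in `morphology_only` bypass the molecular steps entirely
    (pass-through annotation for taxa placed on shell morphology alone).
    When no placement tree is supplied, a neighbor-joining tree of references
    plus queries is built for the sister step.
    """
    if queries.length != ref_aln.length:
        raise ValueError(
            "queries and references must share one alignment coordinate frame"
        )
    morph = set(morphology_only)
    results: list[AssignmentResult] = []
    pending: list[str] = []
    qseqs = queries.unmasked_sequences()
    for q in queries.taxa:
        if q in morph:
            results.append(
                AssignmentResult(q, rule="morphology_only",
                                 notes="attributed on morphology, no molecular step")
            )
            continue
        res = assign_by_threshold(q, qseqs[q], refs, ref_aln, threshold, min_sites)
        # above-threshold (no match, but a defined distance) falls through to
        # the sister step; multi-genus ties stay reported as unresolved
        if res.rule == "unresolved" and res.matched_taxon is None and res.min_distance is not None:
            pending.append(q)
        results.append(res)

    if pending:
        tree = placement
        if tree is None:
            tree = _build_placement_tree(queries, ref_aln, pending)
        for i, res in enumerate(results):
            if res.query not in pending:
                continue
            if tree is None:
                continue
            try:
                sis = assign_by_sister(res.query, tree, refs)
            except UnknownTaxonError:
                continue
            results[i] = AssignmentResult(
                res.query, matched_taxon=res.matched_taxon,
                min_distance=res.min_distance, n_sites=res.n_sites,
                genus=sis.genus, rule=sis.rule,
                notes="; ".join(x for x in (res.notes, sis.notes) if x),
            )
    return results


def _build_placement_tree(
    queries: MultiLocusAlignment,
    ref_aln: MultiLocusAlignment,
    pending: Sequence[str],
) -> PhyloTree | None:
    try:
        merged = MultiLocusAlignment(
            taxa=ref_aln.taxa + tuple(q for q in queries.taxa if q in pending),
            sequences=ref_aln.sequences
            + tuple(queries.sequence(q) for q in queries.taxa if q in pending),
            partitions=ref_aln.partitions,
            mask=ref_aln.mask | queries.mask,
        )
        dm = pairwise_matrix(merged, metric="k2p")
        tree = nj_tree(dm)
        # midpoint-root the unrooted NJ tree: the sister rule needs a root,
        # and rooting at the arbitrary basal join would distort sister groups
        tree.reroot_at_midpoint(update_bipartitions=False)
    except Exception as exc:  # placement is advisory; never abort the run
        log.warning("could not build NJ placement tree: %s", exc)
        return None
    tree.is_rooted = True
    return tree


def write_assignments(results: Sequence[AssignmentResult], path: str | Path) -> None:
    """TSV with columns query, matched_taxon, min_distance, n_sites, genus, rule, notes."""
    with open(path, "w") as fh:
        fh.write("query\tmatched_taxon\tmin_distance\tn_sites\tgenus\trule\tnotes\n")
        for r in results:
            dist = "" if r.min_distance is None else f"{r.min_distance:.6f}"
            fh.write(
                "\t".join(
                    [
                        r.query,
                        r.matched_taxon or "",
                        dist,
                        "" if r.n_sites is None else str(r.n_sites),
                        r.genus or "",
                        r.rule,
                        r.notes,
                    ]
                )
                + "\n"
            )
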