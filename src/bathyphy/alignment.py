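"""Multi-locus nucleotide alignments.

An alignment is a rectangular block of IUPAC nucleotide symbols over a set of
taxa, partitioned into contiguous gene regions, with an optional mask of
columns excluded from downstream distance and likelihood computation.
Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import (
    AlignmentError,
    AlignmentLengthError,
    DuplicateTaxonError,
    EmptyInputError,
    NoInformativeSitesError,
)

#: Unambiguous bases usable by distances and likelihoods.
BASES = frozenset("ACGT")
#: IUPAC ambiguity codes (anything else besides gap/missing is rejected).
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")
#: Full accepted symbol set.
VALID_SYMBOLS = BASES | AMBIGUITY_CODES | frozenset("-?")


@dataclass(frozen=True)
class MultiLocusAlignment:
    """Taxa x concatenated partitioned sites.

    Parameters
    ----------
    taxa : ordered taxon labels (unique).
    sequences : one uppercase string per taxon, all of equal length.
    partitions : ordered ``(name, start, end)`` triples that are disjoint,
        contiguous and cover ``[0, length)``.
    mask : set of excluded column indices.
    """

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]
    partitions: tuple[tuple[str, int, int], ...]
    mask: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa and sequences differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise DuplicateTaxonError(f"duplicate taxon labels: {dupes}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentLengthError(f"ragged alignment, lengths {sorted(lengths)}")
        length = lengths.pop() if lengths else 0
        pos = 0
        for name, start, end in self.partitions:
            if start != pos or end <= start:
                raise AlignmentError(
                    f"partition {name!r} [{start},{end}) not contiguous at {pos}"
                )
            pos = end
        if pos != length:
            raise AlignmentError(f"partitions cover [0,{pos}), alignment length {length}")
        for taxon, seq in zip(self.taxa, self.sequences):
            bad = set(seq) - VALID_SYMBOLS
            if bad:
                raise AlignmentError(f"invalid symbols {sorted(bad)} in {taxon!r}")
        if not all(0 <= i < length for i in self.mask):
            raise AlignmentError("mask indices outside [0, length)")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def sequence(self, taxon: str) -> str:
        try:
            return self.sequences[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(taxon) from None

    def usable_columns(self) -> list[int]:
        """Indices of unmasked columns, ascending."""
        return [i for i in range(self.length) if i not in self.mask]

    def unmasked_sequences(self) -> dict[str, str]:
        """Taxon -> sequence restricted to unmasked columns."""
        cols = self.usable_columns()
        return {t: "".join(s[i] for i in cols) for t, s in zip(self.taxa, self.sequences)}


def read_fasta(path: str | Path, partition_name: str | None = None) -> MultiLocusAlignment:
    """Read one aligned FASTA file as a single-partition alignment.

    Taxa keep file order; sequences are uppercased. Raises
    :class:`AlignmentLengthError` on ragged input, :class:`DuplicateTaxonError`
    on repeated labels and :class:`EmptyInputError` on an empty file.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    taxa = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    name = partition_name if partition_name is not None else path.stem
    length = len(seqs[0])
    return MultiLocusAlignment(taxa, seqs, ((name, 0, length),))


def write_fasta(aln: MultiLocusAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in zip(aln.taxa, aln.sequences):
            fh.write(f">{taxon}\n{seq}\n")


def concatenate_partitions(
    alignments: Sequence[MultiLocusAlignment],
) -> MultiLocusAlignment:
    """Concatenate per-gene alignments into one partitioned supermatrix.

    The taxon set is the union (first-appearance order); a taxon absent from a
    gene gets a ``'?'`` block of that gene's length. Partition intervals are
    recorded per input partition; masks carry over with shifted coordinates.
    """
    if not alignments:
        raise EmptyInputError("no alignments to concatenate")
    taxa: list[str] = []
    for aln in alignments:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    parts: list[tuple[str, int, int]] = []
    mask: set[int] = set()
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    offset = 0
    for aln in alignments:
        for name, start, end in aln.partitions:
            parts.append((name, offset + start, offset + end))
        mask.update(offset + i for i in aln.mask)
        for t in taxa:
            if t in aln.taxa:
                chunks[t].append(aln.sequence(t))
            else:
                chunks[t].append("?" * aln.length)
        offset += aln.length
    seqs = tuple("".join(chunks[t]) for t in taxa)
    return MultiLocusAlignment(tuple(taxa), seqs, tuple(parts), frozenset(mask))


def mask_ambiguous_sites(aln: MultiLocusAlignment) -> MultiLocusAlignment:
    """Extend the mask with every column containing a gap or non-ACGT symbol.

    Column-wise exclusion is deterministic and conservative; per-pair deletion
    remains available in the distances module. Raises
    :class:`NoInformativeSitesError` if nothing survives.
    """
    mask = set(aln.mask)
    for col in range(aln.length):
        if col in mask:
            continue
        if any(seq[col] not in BASES for seq in aln.sequences):
            mask.add(col)
    if len(mask) == aln.length and aln.length > 0:
        raise NoInformativeSitesError("all alignment columns masked")
    return replace(aln, mask=frozenset(mask))


def subset_taxa(aln: MultiLocusAlignment, keep: Iterable[str]) -> MultiLocusAlignment:
    """Restrict the alignment to the given taxa (alignment order preserved)."""
    keep = set(keep)
    idx = [i for i, t in enumerate(aln.taxa) if t in keep]
    missing = keep - set(aln.taxa)
    if missing:
        raise KeyError(f"taxa absent from alignment: {sorted(missing)}")
    return replace(
        aln,
        taxa=tuple(aln.taxa[i] for i in idx),
        sequences=tuple(aln.sequences[i] for i in idx),
    )
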