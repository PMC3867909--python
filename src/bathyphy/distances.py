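"""Pairwise nucleotide distances and neighbor-joining placement trees.

The workhorse is the Kimura 2-parameter (K2P) distance, which corrects
observed divergence separately for transitions (P) and transversions (Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites are compared under pairwise deletion: only positions where both
sequences carry an unambiguous base (A/C/G/T) enter P, Q and the usable-site
count, so reference fragments of unequal coverage remain comparable.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import skbio
from skbio.tree import nj as _skbio_nj

from .alignment import BASES, MultiLocusAlignment
from .errors import (
    IncompleteMatrixError,
    NoComparableSitesError,
    SaturationError,
)
from .trees import PhyloTree, parse_newick

_PURINES = frozenset("AG")


def _count_site_classes(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """(n compared, transitions, transversions) under pairwise deletion."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be equal length (same coordinate frame)")
    n = ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a not in BASES or b not in BASES:
            continue
        n += 1
        if a != b:
            if (a in _PURINES) == (b in _PURINES):
                ts += 1
            else:
                tv += 1
    return n, ts, tv


def k2p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """K2P distance and the number of compared sites.

    Raises :class:`NoComparableSitesError` when no site is comparable and
    :class:`SaturationError` when a logarithm argument is non-positive
    (the correction is undefined for such divergent pairs).
    """
    n, ts, tv = _count_site_classes(seq_a, seq_b)
    if n == 0:
        raise NoComparableSitesError("no site with unambiguous bases in both sequences")
    p, q = ts / n, tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P undefined for P={p:.3f}, Q={q:.3f}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2), n


def p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Uncorrected proportion of mismatching sites (pairwise deletion)."""
    n, ts, tv = _count_site_classes(seq_a, seq_b)
    if n == 0:
        raise NoComparableSitesError("no site with unambiguous bases in both sequences")
    return (ts + tv) / n, n


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric distance matrix; undefined (saturated) pairs are NaN."""

    taxa: tuple[str, ...]
    d: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n) or self.comparable_sites.shape != (n, n):
            raise ValueError("matrix shapes must match the number of taxa")

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.d[i, j])

    @property
    def is_complete(self) -> bool:
        return bool(np.all(np.isfinite(self.d)))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.taxa) + "\n")
            for i, t in enumerate(self.taxa):
                fh.write(t + "\t" + "\t".join(f"{x:.8g}" for x in self.d[i]) + "\n")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for i, t in enumerate(self.taxa):
                fh.write(t + "  " + "  ".join(f"{x:.8f}" for x in self.d[i]) + "\n")


def pairwise_matrix(
    aln: MultiLocusAlignment, metric: str = "k2p"
) -> DistanceMatrix:
    """All-pairs distance matrix over the alignment's unmasked columns.

    Saturated or incomparable pairs are reported as NaN rather than raising,
    so a single rogue pair cannot abort a matrix; consumers that need a
    complete matrix (NJ) check and refuse explicitly.
    """
    if metric not in {"k2p", "p"}:
        raise ValueError(f"unknown metric {metric!r}")
    fn = k2p_distance if metric == "k2p" else p_distance
    seqs = aln.unmasked_sequences()
    taxa = aln.taxa
    m = len(taxa)
    d = np.zeros((m, m))
    n_sites = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            try:
                dij, nij = fn(seqs[taxa[i]], seqs[taxa[j]])
            except (NoComparableSitesError, SaturationError):
                dij, nij = math.nan, 0
            d[i, j] = d[j, i] = dij
            n_sites[i, j] = n_sites[j, i] = nij
    return DistanceMatrix(tuple(taxa), d, n_sites)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree (unrooted) from a complete distance matrix.

    Negative estimated branch lengths are clamped to zero (the placement tree
    is advisory — the genus rule reads its topology, not its lengths).
    """
    if len(dm.taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not dm.is_complete:
        bad = [
            (dm.taxa[i], dm.taxa[j])
            for i in range(len(dm.taxa))
            for j in range(i + 1, len(dm.taxa))
            if not np.isfinite(dm.d[i, j])
        ]
        raise IncompleteMatrixError(f"undefined distances for pairs: {bad[:5]}")
    sk_dm = skbio.DistanceMatrix(dm.d, ids=list(dm.taxa))
    buf = io.StringIO()
    _skbio_nj(sk_dm).write(buf)
    newick = buf.getvalue()
    tree = parse_newick(newick, rooted=False)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree
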