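"""Exception hierarchy.

All package errors derive from :class:`BathyphyError` so callers can catch
one base class at pipeline boundaries.
"""


class BathyphyError(Exception):
    """Base class for all bathyphy errors."""


class AlignmentError(BathyphyError):
    """Invalid alignment (ragged rows, bad symbols, ...)."""


class AlignmentLengthError(AlignmentError):
    """Sequences in one alignment differ in length."""


class DuplicateTaxonError(AlignmentError):
    """Two records share a taxon label."""


class EmptyInputError(BathyphyError):
    """An input file or collection contained no usable records."""


class NoInformativeSitesError(AlignmentError):
    """Every column of an alignment is masked."""


class TreeError(BathyphyError):
    """Invalid tree or tree operation."""


class NewickError(TreeError):
    """Unparseable Newick input."""


class NegativeBranchLengthError(TreeError):
    """A branch length is negative."""


class UnknownTaxonError(BathyphyError):
    """A requested taxon label is absent from the structure queried."""


class NoSisterError(TreeError):
    """The target clade is the whole tree, so it has no sister group."""


class DistanceError(BathyphyError):
    """Pairwise distance undefined or uncomputable."""


class NoComparableSitesError(DistanceError):
    """No site where both sequences carry an unambiguous base."""


class SaturationError(DistanceError):
    """Distance correction undefined (logarithm argument <= 0)."""


class IncompleteMatrixError(DistanceError):
    """A distance matrix contains undefined entries where defined ones are required."""


class CodingError(BathyphyError):
    """A discrete character cannot be coded from the reference table."""


class RecipeError(BathyphyError):
    """A simulation recipe is infeasible or inconsistent."""
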