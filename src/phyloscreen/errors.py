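"""Exception hierarchy shared across the package."""


class PhyloscreenError(Exception):
    """Base class for all package errors."""


class AlignmentError(PhyloscreenError):
    pass


class LengthMismatchError(AlignmentError):
    """Sequences in one alignment differ in length."""


class DuplicateTaxonError(AlignmentError):
    """The same taxon label appears more than once."""


class AlphabetError(AlignmentError):
    """A character is not part of the declared alphabet (strict mode)."""


class EmptyAlignmentError(AlignmentError):
    """An operation produced or received an alignment with no sites."""


class PartitionError(PhyloscreenError):
    pass


class PartitionOverlapError(PartitionError):
    """Two partition ranges claim the same site."""


class PartitionBoundsError(PartitionError):
    """A partition range lies outside the alignment."""


class FrameError(PartitionError):
    """A partition length is incompatible with codon structure."""


class UnknownTaxonError(PhyloscreenError):
    """A referenced taxon is absent from the alignment or tree."""


class DisjointnessError(PhyloscreenError):
    """Taxon groups that must be disjoint overlap, or a group is empty."""


class InsufficientDataError(PhyloscreenError):
    """Not enough observed data to compute the requested statistic."""


class StateError(PhyloscreenError):
    """A character state is not in the declared state list."""


class ConfigError(PhyloscreenError):
    """Invalid or inconsistent run configuration."""
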