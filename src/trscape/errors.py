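"""Exception hierarchy for trscape."""


class TrscapeError(Exception):
    """Base class for all trscape errors."""


class FastaFormatError(TrscapeError):
    """Malformed FASTA input (empty file, duplicate IDs, illegal residues)."""


class AnnotationError(TrscapeError):
    """Malformed or inconsistent gene annotation."""


class MotifError(TrscapeError, ValueError):
    """Invalid motif string (empty, non-ACGT, or too long)."""


class UndefinedContentError(TrscapeError, ValueError):
    """GC content requested for a sequence with no valid nucleotides."""


class DensityError(TrscapeError, ValueError):
    """Density undefined (zero valid nucleotides or zero genome density)."""


class StatsError(TrscapeError, ValueError):
    """Degenerate input to a statistical test."""


class CapacityError(TrscapeError, ValueError):
    """A simulation planting plan exceeds the capacity of a region class."""
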