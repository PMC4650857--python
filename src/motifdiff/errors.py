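"""Exception hierarchy for motifdiff.

All package errors derive from :class:`MotifError`, so callers (and the CLI)
can catch one base class.
"""


class MotifError(Exception):
    """Base class for all motifdiff errors."""


class AlphabetError(MotifError):
    """A symbol is not part of the alphabet, or two alphabets are incompatible."""


class LengthMismatchError(MotifError):
    """Sequences or motifs that must share a common length do not."""


class DegenerateColumnError(MotifError):
    """A motif position carries no counts (all-zero / all-skipped column)."""


class NormalizationError(MotifError):
    """A probability row deviates from sum 1 beyond the allowed tolerance."""


class ShapeError(MotifError):
    """A matrix cannot be oriented to L x |alphabet| under any allowed orientation."""


class ParseError(MotifError):
    """A motif or matrix file is malformed."""


class MeasureLookupError(MotifError, KeyError):
    """An unknown stack-height or symbol-weight name was requested."""
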