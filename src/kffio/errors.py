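"""Exception hierarchy for kffio.

Every error raised by the library derives from :class:`KffError`, so callers
can catch one type at an API boundary and still discriminate when needed.
"""


class KffError(Exception):
    """Base class of every kffio error."""


class InvalidEncodingError(KffError):
    """The four nucleotide codes do not form a permutation of 0..3."""


class AlphabetError(KffError):
    """A sequence contains a character outside {A, C, G, T}."""


class TooShortError(KffError):
    """A sequence is shorter than the window size requested of it."""


class TruncationError(KffError):
    """The byte stream ended before a declared field was complete."""


class NotAKffError(KffError):
    """The stream does not start with the KFF magic bytes."""


class UnknownSectionError(KffError):
    """An unrecognized section-type byte was encountered."""


class OrderingError(KffError):
    """A sequence section appeared before the variables it requires."""


class MissingVariableError(KffError):
    """A required variable (e.g. ``m``) is absent from the variable state."""


class MalformedVariableError(KffError):
    """A variable name or value cannot be represented in a values section."""


class MalformedBlockError(KffError):
    """A block's declared geometry is internally inconsistent."""


class EmptyBlockError(KffError):
    """A block carries zero k-mers."""


class BlockOverflowError(KffError):
    """A block carries more k-mers than the declared ``max``."""


class DuplicateKmerError(KffError):
    """A k-mer appears more than once where uniqueness is required."""


class IncompatibilityError(KffError):
    """Files with conflicting parameters (e.g. differing k) were combined."""


class ParameterError(KffError):
    """A user-supplied parameter is out of its valid range."""


class BrokenIndexError(KffError):
    """An index entry does not resolve to a section of the declared type."""
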