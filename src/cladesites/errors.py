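"""Named exceptions raised across the package.

Every validation failure has its own class so callers (and the CLI) can
distinguish malformed inputs from programming errors.
"""


class CladesitesError(Exception):
    """Base class for all package errors."""


class SchemeError(CladesitesError):
    """Invalid amino-acid category scheme."""


class SchemeOverlapError(SchemeError):
    """A residue appears in more than one category."""


class SchemeIncompleteError(SchemeError):
    """The categories do not cover all 20 standard residues."""


class SchemeUnknownResidueError(SchemeError):
    """A category lists a character outside the 20 standard residues."""


class RaggedAlignmentError(CladesitesError):
    """Alignment rows have unequal lengths."""


class DuplicateSequenceError(CladesitesError):
    """The same sequence id occurs more than once."""


class UnmappedSequenceError(CladesitesError):
    """A sequence id has no clade assignment."""


class ColumnOutOfRangeError(CladesitesError, IndexError):
    """A 1-based alignment column index is out of range."""


class ReferenceError_(CladesitesError, KeyError):
    """A named reference sequence is absent from the alignment."""


class DomainRangeError(CladesitesError):
    """A residue position falls outside the annotated reference length."""


class HitParseError(CladesitesError):
    """A similarity-search tabular file is malformed (carries line number)."""


class EmptyGroupError(CladesitesError):
    """An isoform group with no members."""


class NoComparableColumnsError(CladesitesError):
    """No gap-free columns remain after complete deletion."""


class UnknownLeafError(CladesitesError, KeyError):
    """A leaf label is absent from the tree."""


class UnsatisfiableSpecError(CladesitesError):
    """A synthetic family specification cannot be realised."""
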