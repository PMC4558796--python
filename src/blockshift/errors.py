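"""Exception hierarchy.

All user-input problems raise :class:`InputError` subclasses so the CLI can
map them to distinct exit codes without string matching.
"""


class BlockshiftError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(BlockshiftError):
    """Malformed or inconsistent user input (files, sequences, alignments)."""

    exit_code = 2


class AlignmentError(InputError):
    """A pairwise alignment violates its invariants."""


class StructureError(InputError):
    """A structure file cannot be parsed or lacks the requested chain."""


class MatrixError(InputError):
    """A substitution or contact-energy matrix is malformed."""


class ModeError(BlockshiftError):
    """A refinement mode is unknown or not implemented."""

    exit_code = 3
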