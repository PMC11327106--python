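"""Exception hierarchy.

Exit-code mapping used by the CLI: missing input -> 2, validation
failure -> 3, internal invariant breach -> 4.
"""


class IgkError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class MissingInputError(IgkError):
    """A required input file or key is absent."""

    exit_code = 2


class ValidationError(IgkError):
    """An input violates a documented precondition or format contract."""

    exit_code = 3


class InvariantError(IgkError):
    """An internal consistency check failed; indicates a bug."""

    exit_code = 4
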