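"""Exception hierarchy.

ValidationError covers malformed user input (bad specs, misaligned files,
infeasible parameters); RuntimeFailure covers errors arising mid-computation.
The CLI maps them to exit codes 1 and 2 respectively.
"""


class SwarmvoteError(Exception):
    """Base class for all package errors."""


class ValidationError(SwarmvoteError, ValueError):
    """Invalid input: bad field values, shape mismatches, malformed files."""


class RuntimeFailure(SwarmvoteError, RuntimeError):
    """Failure during computation (degenerate images, empty masks, ...)."""
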