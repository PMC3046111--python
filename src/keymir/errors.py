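"""Exception hierarchy shared by all keymir stages.

The CLI maps these onto exit codes: :class:`InputError` and
:class:`ParameterError` exit with 2, :class:`ConvergenceError` with 3.
"""


class KeymirError(Exception):
    """Base class for all keymir errors."""


class InputError(KeymirError):
    """Malformed or inconsistent input data (bad file line, missing group,
    identifier-space mismatch, empty network after filtering)."""


class ParameterError(KeymirError):
    """A parameter outside its documented range (e.g. fold threshold <= 1)."""


class ConvergenceError(KeymirError):
    """The equilibrium solver failed to reach the requested residual."""

    def __init__(self, message: str, residual: float | None = None,
                 iterations: int | None = None):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class UndefinedResultError(KeymirError):
    """A quantity is undefined on this input (too few points, zero variance,
    empty target set)."""


class NotFoundError(KeymirError):
    """A requested object does not exist (empty module list, unknown node)."""
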