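"""Exception hierarchy shared across the package."""


class PBAError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PBAError, ValueError):
    """An argument is outside its documented domain."""


class InconsistentDataError(PBAError, ValueError):
    """The supplied summary statistics admit no distribution on [a, b]."""


class ModelError(PBAError, RuntimeError):
    """A structural problem with a cohort model (bad rows, unreachable absorption)."""


class EvaluationError(PBAError, RuntimeError):
    """A black-box model returned a non-finite value.

    Carries the offending parameter vector in ``vector``.
    """

    def __init__(self, message, vector=None):
        super().__init__(message)
        self.vector = vector
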