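"""Exception hierarchy shared across the package."""


class DmadError(Exception):
    """Base class for all package errors."""


class DomainError(DmadError, ValueError):
    """An argument is outside its mathematical domain (e.g. lam not in [0, 1])."""


class InputError(DmadError, ValueError):
    """Structurally invalid input (mismatched atom lists, bad partitions, ...)."""


class ParameterError(DmadError, KeyError):
    """A required parameter (e.g. a solvation sigma for an element) is missing."""


class FitError(DmadError, RuntimeError):
    """A least-squares or nonlinear fit failed or is ill-posed."""


class NumericalError(DmadError, RuntimeError):
    """A nonfinite value appeared during iteration; carries the iteration index."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration
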