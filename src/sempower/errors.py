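"""Exception types shared across the package."""


class SempowerError(Exception):
    """Base class for package errors."""


class InvalidParameterError(SempowerError, ValueError):
    """A model or design parameter is outside its admissible range."""


class DegeneracyError(SempowerError, ValueError):
    """A covariance matrix required to be positive definite is not.

    Carries the offending eigenvalue when known.
    """

    def __init__(self, message: str, eigenvalue: float | None = None):
        super().__init__(message)
        self.eigenvalue = eigenvalue


class UnderIdentifiedError(SempowerError, ValueError):
    """A fitted model pattern has more free parameters than sample moments."""


class ModelSyntaxError(SempowerError, ValueError):
    """A model-string could not be parsed."""
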