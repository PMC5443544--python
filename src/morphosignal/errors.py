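"""Exception hierarchy shared across the package."""


class MorphosignalError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MorphosignalError):
    """A landmark or tree file could not be parsed."""


class SchemaError(MorphosignalError):
    """A tabular input is missing mapped columns or has an invalid layout."""


class ValidationError(MorphosignalError):
    """A dataset violates an invariant (inconsistent k, duplicate ids, ...)."""


class DegenerateShapeError(MorphosignalError):
    """All landmarks coincide; centroid size is zero and shape is undefined."""


class ConvergenceError(MorphosignalError):
    """Iterative superimposition failed to converge.

    Carries the last root-mean-square consensus change in ``last_delta``.
    """

    def __init__(self, message: str, last_delta: float | None = None):
        super().__init__(message)
        self.last_delta = last_delta


class DimensionError(MorphosignalError):
    """A requested subspace dimension exceeds the usable rank.

    ``usable_rank`` tells the caller the largest dimension that would work.
    """

    def __init__(self, message: str, usable_rank: int | None = None):
        super().__init__(message)
        self.usable_rank = usable_rank


class ParameterError(MorphosignalError):
    """An argument is outside its admissible range."""
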