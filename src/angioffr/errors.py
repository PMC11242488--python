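"""Exception hierarchy.

All package errors derive from :class:`AngioFFRError` so callers (and the
CLI exit-code mapping) can distinguish input-validation problems from
image-quality failures.
"""


class AngioFFRError(Exception):
    """Base class for all package errors."""


class ProfileValidationError(AngioFFRError, ValueError):
    """A centerline profile violates its invariants (ordering, positivity)."""


class DegenerateFitError(AngioFFRError, ValueError):
    """Too few samples survive exclusion to fit a reference-diameter line."""


class DomainError(AngioFFRError, ValueError):
    """A scalar argument is outside its physical domain."""


class ConfigurationError(AngioFFRError, ValueError):
    """A model/run configuration violates its invariants."""


class SingularGeometryError(AngioFFRError, ValueError):
    """A lesion with zero minimal area cannot carry flow."""


class TraceFailureError(AngioFFRError, RuntimeError):
    """Centerline tracing could not lock onto the vessel near a seed."""

    def __init__(self, message: str, seed_index: int | None = None):
        super().__init__(message)
        self.seed_index = seed_index


class QualityFailureError(AngioFFRError, RuntimeError):
    """Too many diameter samples were unmeasurable on the image."""


class JoinError(AngioFFRError, ValueError):
    """Case identifiers of two evaluation tables could not be matched."""

    def __init__(self, message: str, offenders: list | None = None):
        super().__init__(message)
        self.offenders = offenders or []
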