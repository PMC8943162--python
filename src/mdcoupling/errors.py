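"""Exception hierarchy shared across the package."""


class MDCouplingError(Exception):
    """Base class for all package errors."""


class FormatError(MDCouplingError):
    """A file could not be parsed; carries the offending line number when known."""


class EmptyInputError(MDCouplingError):
    """An input contained no usable records."""


class ShapeError(MDCouplingError):
    """Coordinate array shapes disagree with the topology."""


class SelectionError(MDCouplingError):
    """An atom selection could not be resolved."""


class DegeneracyError(MDCouplingError):
    """A point set is too degenerate for a rigid superposition."""


class InsufficientFramesError(MDCouplingError):
    """An estimator needs more trajectory frames than were supplied."""


class InvalidCovarianceError(MDCouplingError):
    """A covariance matrix is not symmetric positive semi-definite."""


class AggregationError(MDCouplingError):
    """Mutual-information matrices could not be combined."""


class SpecError(MDCouplingError):
    """A synthetic-data specification is invalid."""


class LookupFailure(MDCouplingError):
    """A residue or atom named in a request is absent from the topology."""
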