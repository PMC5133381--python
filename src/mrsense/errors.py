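"""Exception hierarchy shared across the package."""


class MRDataError(ValueError):
    """Base class for problems with summarized MR data."""


class SchemaError(MRDataError):
    """An input table is missing a required column."""


class ValidationError(MRDataError):
    """A dataset or row violates an invariant (non-positive SE, duplicate id, ...)."""


class OrientationError(MRDataError):
    """Orientation is undefined (a variant has a null exposure association)."""


class EstimationError(ValueError):
    """An estimator's preconditions are not met."""


class InsufficientVariantsError(EstimationError):
    """Fewer variants than the method requires."""


class NotIdentifiedError(EstimationError):
    """The estimator is not identified on this dataset."""
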