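"""Exception hierarchy for the pipeline.

Every failure mode raised by cytopipe derives from :class:`CytopipeError`,
so callers can catch one type at a pipeline boundary.  Subclasses are
deliberately specific: the error type tells you which contract was broken.
"""


class CytopipeError(Exception):
    """Base class for all cytopipe errors."""


class UnsupportedFormatError(CytopipeError):
    """File is not an FCS version this package reads (3.0 / 3.1)."""


class IntegrityError(CytopipeError):
    """A file's declared structure disagrees with its actual content."""


class ChannelLookupError(CytopipeError, KeyError):
    """A channel name was not found in the panel."""


class DimensionError(CytopipeError, ValueError):
    """Array shape/length mismatch."""


class ParameterError(CytopipeError, ValueError):
    """A transformation or model parameter violates its constraint."""


class EstimationError(CytopipeError):
    """Too little data for a statistical estimate."""


class SpilloverParseError(CytopipeError):
    """Malformed $SPILLOVER / SPILL keyword."""


class ConstraintError(CytopipeError):
    """Attempt to modify an immutable element (e.g. spillover diagonal)."""


class AvailabilityError(CytopipeError):
    """Required per-sample metadata (e.g. spillover keyword) is absent."""


class NumericalError(CytopipeError):
    """A numerically singular or ill-conditioned operation."""


class NormalizationInfeasibleError(CytopipeError):
    """Too many samples need manual peak overrides for a channel."""


class WarpError(CytopipeError):
    """Landmark warp would be non-monotone for a sample/channel."""


class DependencyError(CytopipeError):
    """A gate's parent population tag does not exist."""


class InfeasibilityError(CytopipeError):
    """An operation cannot satisfy its quota/size preconditions."""


class DegenerateChannelError(CytopipeError):
    """A channel is constant where spread is required (e.g. rescaling)."""
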