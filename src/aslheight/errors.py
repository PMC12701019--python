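"""Exception hierarchy shared across the pipeline.

Stage failures that should exclude a single position from a well mean are
raised as specific subclasses so that :func:`aslheight.heights.measure_position`
can convert them into QC flags instead of aborting a whole well.
"""


class ASLError(Exception):
    """Base class for all package errors."""


class InvalidIndexError(ASLError, ValueError):
    """A refractive index below 1.0 was supplied."""


class GeometryError(ASLError, ValueError):
    """Phantom geometry does not fit into the requested stack depth."""


class InsufficientPeaksError(ASLError):
    """Fewer than three reflection peak candidates were found."""


class FitFailureError(ASLError):
    """Gaussian peak fit did not converge."""


class BoundaryFailureError(ASLError):
    """No half-maximum crossing on one or both sides of a fluorescence band."""


class MethodUnavailableError(ASLError):
    """A channel required by the selected measurement method is missing."""


class InsufficientDataError(ASLError):
    """Too few usable positions to summarise a well."""


class ConfigurationError(ASLError, ValueError):
    """Invalid or inconsistent run configuration."""
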