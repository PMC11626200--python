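"""Exception hierarchy.

All package errors derive from :class:`VesimapError` so callers can catch
one base class; the CLI maps validation errors to exit code 2 and runtime
errors to exit code 1.
"""


class VesimapError(Exception):
    """Base class for all vesimap errors."""


class FormatError(VesimapError):
    """A file or table does not conform to the documented format."""


class ConfigurationError(VesimapError):
    """Invalid or inconsistent configuration / parameters."""


class DegenerateGeometryError(VesimapError):
    """Geometric input admits no well-posed solution (parallel axes,
    rank-deficient sphere fit, particle coincident with a center, ...)."""


class UndefinedCorrelationError(VesimapError):
    """Correlation requested on a constant variable."""
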