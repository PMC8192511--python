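"""Exception hierarchy shared across the package."""


class KeltrackError(Exception):
    """Base class for all package errors."""


class FormatError(KeltrackError):
    """A file does not conform to the documented layout (missing columns/variables)."""


class ValidationError(KeltrackError):
    """Well-formed input violates a domain invariant (negative depth, land/bathy clash)."""


class ConfigError(KeltrackError):
    """A configuration value is out of its declared range."""


class GridError(KeltrackError):
    """State-grid construction failed (e.g. all-land domain)."""


class ShapeError(KeltrackError):
    """Arrays from different grids or of mismatched length were combined."""
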