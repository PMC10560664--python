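"""Exception hierarchy shared across the package."""


class GazeloadError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GazeloadError, ValueError):
    """A file does not conform to the expected tabular layout."""


class DataError(GazeloadError, ValueError):
    """Structurally valid input violating a data contract (e.g. non-monotone time)."""


class UndefinedMetricError(GazeloadError, ValueError):
    """A metric's denominator is empty (e.g. zero valid samples)."""


class ConfigError(GazeloadError, ValueError):
    """Inconsistent or incomplete configuration."""


class DegenerateGeometryError(GazeloadError, ValueError):
    """Too few distinct points for a tessellation."""
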