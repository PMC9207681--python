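"""Exception hierarchy for memfield."""


class MemfieldError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MemfieldError):
    """A file could not be parsed; carries file/line context in the message."""


class ConfigError(MemfieldError):
    """Invalid, unknown, or out-of-range configuration value."""


class SelectionError(MemfieldError):
    """An atom/residue/segment selection did not resolve against a topology."""


class ConvergenceError(MemfieldError):
    """An iterative solver or fit failed to converge."""


class GeometryError(MemfieldError):
    """Degenerate geometry (collinear points, empty selection, zero radius)."""


class RateUnidentifiableError(MemfieldError):
    """A kinetic trace carries no decay information (e.g. constant signal)."""
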