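"""Exception hierarchy shared by all modules."""


class CmbError(Exception):
    """Base class for all package errors."""


class FormatError(CmbError):
    """A file could not be read or written in the expected format."""


class ValidationError(CmbError):
    """An input violates a documented contract (value set, shape, range)."""


class GeometryError(CmbError):
    """Grid geometries or affines are inconsistent or degenerate."""
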