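"""Exception hierarchy."""


class GwasRepError(Exception):
    """Base class for all package errors."""


class CatalogFormatError(GwasRepError):
    """An input file does not conform to its declared dialect."""


class RecordError(GwasRepError):
    """A single record violates its contract (e.g. a publication with no authors)."""


class ConfigError(GwasRepError):
    """Invalid run or generator configuration."""


class EmptyTableError(GwasRepError):
    """A proportion table was requested over an empty denominator."""


class InsufficientDataError(GwasRepError):
    """Too few observations for the requested statistical procedure."""


class ConvergenceError(GwasRepError):
    """Iterative fit failed to converge; carries the optimizer trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
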