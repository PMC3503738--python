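"""Exception hierarchy shared across the package."""


class CalfPKPDError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CalfPKPDError, ValueError):
    """A model parameter or configuration value violates its invariants."""


class InsufficientDataError(CalfPKPDError, ValueError):
    """Too few usable observations for the requested operation."""


class StrippingError(CalfPKPDError, RuntimeError):
    """Curve stripping could not separate the exponential phases."""


class ModelSelectionError(CalfPKPDError, RuntimeError):
    """No converged candidate fit was available to select from."""


class ParseError(CalfPKPDError, ValueError):
    """A CSV/config input was malformed; message names the offending line."""
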