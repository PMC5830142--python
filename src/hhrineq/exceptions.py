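"""Exception hierarchy.

Everything derives from :class:`HHRIneqError` so callers can catch the
package's failures with one clause; the leaves mirror the kinds of misuse
the API distinguishes (bad configuration vs. bad data vs. a quantity that
is mathematically undefined for the input).
"""


class HHRIneqError(Exception):
    """Base class for all errors raised by hhrineq."""


class ConfigurationError(HHRIneqError, ValueError):
    """A configuration object is internally inconsistent (names the field)."""


class ValidationError(HHRIneqError, ValueError):
    """Input data violate a documented precondition."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested computation."""


class SchemaError(HHRIneqError, ValueError):
    """A table is missing required columns or has the wrong layout."""


class ParseError(HHRIneqError, ValueError):
    """A value in an input file could not be parsed (carries row context)."""


class DomainError(HHRIneqError, ValueError):
    """The requested quantity is undefined for this input (e.g. mean <= 0)."""


class EstimationError(HHRIneqError, ValueError):
    """A model could not be estimated (e.g. collinear design)."""
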