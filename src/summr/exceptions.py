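"""Exception hierarchy.

All summr errors derive from :class:`SummrError` so callers (and the CLI)
can map failure classes to exit codes without string matching.
"""


class SummrError(Exception):
    """Base class for all summr errors."""


class ConfigurationError(SummrError, ValueError):
    """A user-supplied configuration is unusable (bad column map, bad grid, ...)."""


class ValidationError(SummrError, ValueError):
    """Input data violate a domain invariant (non-positive SE, duplicate ids, ...)."""


class NullInstrumentError(ValidationError):
    """A variant has a zero instrument-exposure association; its ratio is undefined."""


class NumericalError(SummrError, ArithmeticError):
    """A fit or extrapolation could not be computed (singular design, ...)."""
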