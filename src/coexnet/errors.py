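"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`CoexnetError`
so callers can catch one type at pipeline level. Errors that are also argument
problems additionally derive from ``ValueError``.
"""


class CoexnetError(Exception):
    """Base class for all coexnet errors."""


class ConfigurationError(CoexnetError, ValueError):
    """Inconsistent or out-of-range configuration."""


class ParseError(CoexnetError, ValueError):
    """Malformed input file; message carries the offending line where known."""


class DegenerateInputError(CoexnetError, ValueError):
    """Input that makes the requested statistic undefined (e.g. zero variance)."""


class EmptyResultError(CoexnetError):
    """An operation legitimately ran but produced an empty result."""


class UndefinedCorrelationError(CoexnetError, ValueError):
    """Too few usable observations to define a correlation."""
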