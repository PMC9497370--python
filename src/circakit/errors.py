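"""Exception hierarchy for circakit.

All errors raised by the library derive from :class:`CircakitError`, so a
pipeline driver can catch one type and annotate it with the stage name.
"""


class CircakitError(Exception):
    """Base class for all circakit errors."""


class ConfigurationError(CircakitError, ValueError):
    """Invalid simulation or analysis configuration."""


class SchemaError(CircakitError, ValueError):
    """A tabular input violates the documented schema."""


class InsufficientDataError(CircakitError, ValueError):
    """Too few observations for the requested estimate or test."""


class DegenerateFitError(CircakitError, ValueError):
    """The model cannot be fit (e.g. constant response, zero variance)."""


class UndefinedMetricError(CircakitError, ValueError):
    """A metric is mathematically undefined for this input."""
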