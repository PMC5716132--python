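"""Exception hierarchy for srscone.

All srscone-raised errors derive from :class:`SrsConeError` so callers (and the
CLI) can catch package failures without masking programming errors.
"""


class SrsConeError(Exception):
    """Base class for all srscone errors."""


class DomainError(SrsConeError, ValueError):
    """An input lies outside the physical domain of an operation."""


class ConfigurationError(SrsConeError, ValueError):
    """A numerical or run configuration is internally inconsistent."""


class ValidationError(SrsConeError, ValueError):
    """Structured input (scan request, metadata, table) fails validation."""


class RangeError(SrsConeError, ValueError):
    """A lookup/interpolation was requested outside the sampled range."""


class MetricError(SrsConeError, ValueError):
    """A profile does not admit the requested metric (e.g. non-unimodal)."""


class SelectionError(SrsConeError, ValueError):
    """No candidate satisfies a selection rule (e.g. intermediate cone)."""


class NormalizationError(SrsConeError, ValueError):
    """A normalization anchor (e.g. the 20 mm entry) is missing or zero."""


class AssemblyError(SrsConeError, ValueError):
    """A table cannot be assembled because inputs are incomplete."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class ParseError(SrsConeError, ValueError):
    """A file does not conform to the documented dialect."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
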