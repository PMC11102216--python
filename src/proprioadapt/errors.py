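"""Exception hierarchy for the assessment pipeline.

Every stage raises a subclass of :class:`ProprioAdaptError`, so callers can
trap pipeline failures without catching unrelated exceptions.
"""


class ProprioAdaptError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ProprioAdaptError, ValueError):
    """An argument violates a documented precondition."""


class NoOnsetError(ProprioAdaptError):
    """Movement onset could not be detected (no motion in the trace)."""


class TruncatedTrialError(ProprioAdaptError):
    """A probe time falls outside the recorded trajectory span."""


class IncompleteProtocolError(ProprioAdaptError):
    """Trial data do not cover the full task protocol."""


class UndefinedMetricsError(ProprioAdaptError):
    """Metrics cannot be computed (e.g. every trial failed)."""


class ProtocolError(ProprioAdaptError):
    """A session does not match the expected phase structure."""


class DegenerateNormativeError(ProprioAdaptError):
    """Normative data carry no variance (or non-positive RSS) for a variable."""


class InsufficientNormativeError(ProprioAdaptError):
    """Too few normative/control observations to fit reference ranges."""


class UndefinedCorrelationError(ProprioAdaptError):
    """Correlation undefined because an input is constant."""


class DegenerateCovariateError(ProprioAdaptError):
    """Partial correlation undefined: covariate perfectly correlated with an input."""


class SchemaError(ProprioAdaptError, KeyError):
    """A required variable/column is missing from the input table."""
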