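"""Exception hierarchy for the QC pipeline.

All package errors derive from :class:`QCError` so callers (and the CLI)
can distinguish data problems from programming errors.
"""


class QCError(Exception):
    """Base class for all westgardqc errors."""


class FormatError(QCError):
    """A file does not have the expected structure (missing columns, bad header)."""


class ValidationError(QCError):
    """Data is structurally readable but violates an invariant (non-numeric
    value, duplicate run index, unordered series)."""


class InsufficientDataError(QCError):
    """Too few observations to compute the requested statistic (n < 2)."""


class UndefinedCVError(QCError):
    """CV is undefined because the lot mean is zero."""


class DegenerateLimitsError(QCError):
    """Control limits with zero applied SD: every rule would be vacuous."""


class FixtureIntegrityError(QCError):
    """The packaged reference table failed its shape/consistency checks."""


class ConfigurationError(QCError):
    """A pipeline configuration is inconsistent with the supplied data
    (e.g. a chart lacking the second control lot)."""


class QCWarning(UserWarning):
    """Non-fatal diagnostics, e.g. fewer than 20 runs used to establish limits."""
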