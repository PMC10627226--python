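"""Exception hierarchy for the ojip package.

All package errors derive from :class:`OjipError`, so callers (and the CLI)
can distinguish data/validation problems (exit code 1) from usage problems
(exit code 2, raised as :class:`UsageError`).
"""


class OjipError(Exception):
    """Base class for all ojip errors."""


class FormatError(OjipError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(OjipError):
    """Data violates a structural invariant (e.g. non-increasing times)."""


class DegenerateTraceError(OjipError):
    """A transient has no usable variable fluorescence (Fm ~ F0)."""


class FiducialGapError(OjipError):
    """No grid sample lies within tolerance of a requested landmark time."""


class DomainError(OjipError):
    """A formula's denominator vanished or an argument left its domain."""


class DesignError(OjipError):
    """The experimental design cannot support the requested analysis."""


class ConfigurationError(OjipError):
    """A configuration file or option set is inconsistent."""


class UsageError(OjipError):
    """The caller invoked an operation incorrectly (maps to CLI exit 2)."""
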