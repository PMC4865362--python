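"""Exception hierarchy.

Validation problems (bad input data, violated invariants) derive from
:class:`ValidationError` and map to CLI exit code 2; anything else that
escapes is an internal error (exit code 1).
"""


class HydroxymetaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HydroxymetaError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(HydroxymetaError):
    """Input data violates a documented invariant (names the offending rows)."""


class UndefinedRateError(HydroxymetaError):
    """A rate or level is requested over an empty selection (zero coverage)."""


class DegenerateTableError(HydroxymetaError):
    """A contingency table has a zero margin; the test statistic is undefined."""
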