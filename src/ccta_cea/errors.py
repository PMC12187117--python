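"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes (configuration 2, data 3,
numeric/invariant 4).
"""


class CeaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CeaError):
    """A setting or parameter file is malformed, incomplete, or inconsistent."""


class DataError(CeaError):
    """An input table (cohort, survey, rates) is missing or invalid."""


class NumericError(CeaError):
    """A numeric invariant was violated (probabilities, row sums, rates)."""


class InvalidRateError(NumericError):
    """A rate-to-probability conversion produced a value outside [0, 1]."""
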