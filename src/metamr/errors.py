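"""Exception hierarchy.

Config errors, data errors and empty-result conditions are distinguished so
the CLI can map them onto distinct exit codes.
"""


class MetamrError(Exception):
    """Base class for all package errors."""


class ConfigError(MetamrError):
    """Invalid configuration or impossible simulation targets."""


class DataError(MetamrError):
    """Input data violates an invariant (e.g. per-SNP R^2 >= 1)."""


class SumstatsFormatError(DataError):
    """Summary-statistics file is missing mandatory columns."""


class EmptyInputError(DataError):
    """A table contained zero valid rows."""


class EmptyHarmonizationError(DataError):
    """Exposure and outcome share no SNPs."""


class InsufficientInstrumentsError(DataError):
    """Too few instruments for the requested estimator."""


class DegenerateInstrumentError(DataError):
    """An instrument with a zero exposure effect makes the Wald ratio undefined."""
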