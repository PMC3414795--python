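"""Exception hierarchy shared across the package.

All errors derive from :class:`ValueError` so callers that do not care about
the distinction can catch broadly; the CLI maps them onto exit codes
(input errors -> 2, configuration errors -> 3).
"""


class TwolibError(ValueError):
    """Base class for all package errors."""


class InputDomainError(TwolibError):
    """A value is outside the mathematical domain of an operation
    (negative count, fractional count, zero library size, p outside [0, 1])."""


class InputFormatError(TwolibError):
    """A file or table is structurally malformed (bad TSV row, duplicate
    gene ids, undecodable FASTQ qualities)."""


class ConfigurationError(TwolibError):
    """A run-time configuration value is invalid (non-positive floor,
    degenerate simulation scenario, zero weights)."""
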