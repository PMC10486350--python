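"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigurationError -> 2,
ValidationError / FormatError -> 3.
"""


class GlutenScanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GlutenScanError):
    """Invalid or inconsistent configuration (unknown enzyme, empty motif list...)."""


class ValidationError(GlutenScanError):
    """Input data violates a documented invariant (bad residue, negative area...)."""


class FormatError(GlutenScanError):
    """A file does not conform to its expected format."""


class GenerationError(GlutenScanError):
    """The synthetic-data generator could not satisfy its constraints."""
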