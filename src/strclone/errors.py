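"""Exception taxonomy shared across the package.

``ValidationError`` covers malformed configuration or arguments (CLI exit
code 2); ``DataError`` covers structurally broken input data (exit code 3).
"""


class StrcloneError(Exception):
    """Base class for all package errors."""


class ValidationError(StrcloneError, ValueError):
    """Invalid configuration, arguments, or parameter values."""


class DataError(StrcloneError, ValueError):
    """Malformed or inconsistent input data."""


class AlleleParseError(DataError):
    """An allele designation string could not be parsed."""


class StructuralMismatchError(DataError):
    """A child profile carries a locus its designated parent lacks."""


class NullProfileError(DataError):
    """A locus shows no alleles at all: amplification dropout, not biology."""


class ZeroCellError(ValidationError):
    """A 2x2 cell is zero and no continuity correction was requested."""
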