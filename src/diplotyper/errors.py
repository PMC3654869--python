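"""Exception hierarchy shared across the pipeline."""


class DiplotyperError(Exception):
    """Base class for all package errors."""


class FormatError(DiplotyperError):
    """A file does not follow its declared text dialect."""


class DataError(DiplotyperError):
    """Input values are syntactically valid but scientifically unusable."""


class ConfigurationError(DiplotyperError):
    """A parameter or column request cannot be honoured."""


class UndefinedLDError(DataError):
    """LD statistics are undefined (e.g. a monomorphic SNP)."""


class ClusterSizeError(ConfigurationError):
    """Refusing exhaustive 2^n enumeration for too many haplotypes."""


class CollinearityError(DataError):
    """A regression design matrix is rank deficient."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"design matrix is rank deficient; offending column: {column}")


class SeparationError(DataError):
    """Complete separation in a logistic fit; the MLE does not exist."""
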