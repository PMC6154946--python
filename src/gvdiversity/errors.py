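"""Exception hierarchy shared across the pipeline.

Two broad classes matter to callers (and to the CLI exit codes): problems
with the configuration or requested parameters (:class:`ConfigError`) and
problems with the data itself (:class:`DataError`).
"""


class GvDiversityError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GvDiversityError):
    """Invalid configuration, parameters, or requested simulation layout."""


class DataError(GvDiversityError):
    """Malformed or inconsistent input data."""


class GenomeFormatError(DataError):
    """FASTA input does not contain exactly one sequence record."""


class AlphabetError(DataError):
    """Sequence contains characters outside {A, C, G, T, N}."""


class AnnotationError(DataError):
    """An ORF annotation violates its invariants."""


class UnsupportedVariantError(DataError):
    """A variant kind the requested operation does not handle (e.g. indels
    passed to the codon-effect classifier)."""


class UndefinedCorrelationError(DataError):
    """Pearson correlation requested on degenerate input (n < 2 or zero
    variance); reported as an error rather than silently returning 0."""
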