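"""Exception hierarchy shared across the package."""


class SeqboostError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(SeqboostError):
    """Input text is not valid FASTA."""


class EmptySequenceError(SeqboostError):
    """A record has no residues left after sanitization."""


class AmbiguousBaseError(SeqboostError):
    """Non-ACGT character encountered under the reject policy."""


class ConfigError(SeqboostError):
    """Invalid configuration value (unknown scheme, bad k-gap family, ...)."""


class DegenerateLabelsError(SeqboostError):
    """A training set contains only one class."""


class DegenerateSpectrumError(SeqboostError):
    """All-zero power spectrum: ratio descriptors are undefined."""


class UndefinedMetricError(SeqboostError):
    """A metric is undefined for the given inputs (e.g. single-class AUC)."""


class UndefinedRatioError(SeqboostError):
    """A ratio feature with zero denominator (e.g. AT/GC on a GC-free sequence)."""


class DataLeakError(SeqboostError):
    """Record ids overlap between the positive set and a negative batch."""


class ShapeError(SeqboostError):
    """Array dimensions do not match the trained model or schema."""
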