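"""Exception hierarchy shared across the package."""


class LocusPrioError(Exception):
    """Base class for all package-specific errors."""


class VcfParseError(LocusPrioError):
    """A VCF record or header line could not be parsed."""


class VcfFormatError(LocusPrioError):
    """The VCF is structurally unusable (e.g. no genotype columns)."""


class PedigreeError(LocusPrioError):
    """Invalid pedigree file or pedigree structure."""


class IntervalError(LocusPrioError):
    """Invalid genomic interval input (e.g. BED start >= end)."""


class FrequencyTableError(LocusPrioError):
    """Invalid population-frequency table input."""


class NormalizationError(LocusPrioError):
    """Variant normalization failed (reference context unavailable)."""


class AnnotationError(LocusPrioError):
    """Functional classification failed (e.g. codon requested without context)."""


class ConfigurationError(LocusPrioError):
    """An analysis was configured inconsistently (e.g. empty affected cohort)."""


class GeneModelError(LocusPrioError):
    """Invalid transcript/gene model definition."""


class PwmError(LocusPrioError):
    """Invalid position-weight-matrix input or scan request."""
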