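"""Typed exceptions raised by the pipeline.

Every malformed input raises one of these; nothing is silently coerced.
"""


class OmicloadError(Exception):
    """Base class for all package errors."""


class ValidationError(OmicloadError):
    """An input violated a structural contract."""


class TableFormatError(ValidationError):
    """A delimited-text table could not be parsed as required."""


class DuplicateGeneError(ValidationError):
    """A matrix contained repeated gene identifiers."""


class MissingValueError(ValidationError):
    """A non-numeric or missing cell was found and imputation was off."""


class ZeroVarianceError(ValidationError):
    """A column had no variance and cannot be z-scored."""


class LayerPairingError(ValidationError):
    """Condition/layer columns could not be paired as transcript+protein."""


class AnnotationError(ValidationError):
    """A gene-to-pathway annotation table was malformed or unusable."""


class ConfigError(ValidationError):
    """A generator or pipeline configuration was invalid."""
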