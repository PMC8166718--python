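"""Exception hierarchy shared across the package."""


class LumensegError(Exception):
    """Base class for all package errors."""


class InputError(LumensegError):
    """Invalid input data (missing path, mismatched lengths, bad values)."""


class EmptySequenceError(InputError):
    """A frame sequence with no decodable frames."""


class FormatError(LumensegError):
    """Inconsistent or unsupported on-disk format."""


class AlignmentError(LumensegError):
    """Spatially or temporally misaligned arrays."""


class ShapeError(LumensegError):
    """Array shape incompatible with a model or operation."""


class ConfigError(LumensegError):
    """Invalid configuration or specification."""


class DivergenceError(LumensegError):
    """Training produced a non-finite loss."""


class DependencyError(LumensegError):
    """A required artifact (e.g. checkpoint) is missing."""
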