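"""Exception hierarchy shared by all stages."""


class CmafError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CmafError):
    """Malformed on-disk matrix file (ragged rows, empty matrix, bad header)."""


class IdentifierError(CmafError):
    """Duplicate, missing, or unknown entity identifier."""


class MatrixValueError(CmafError):
    """A matrix entry violates its contract (non-finite, out of range, non-binary)."""


class ShapeError(CmafError):
    """Incompatible matrix dimensions or misaligned vocabularies."""


class NumericalError(CmafError):
    """A numerical routine failed to produce a finite, converged result."""


class ValidationError(CmafError):
    """Invalid configuration or hyperparameter value."""
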