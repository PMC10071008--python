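"""Exception hierarchy.

All errors raised by ventriflow derive from :class:`VentriflowError` so callers
can catch the package's failures without masking programming errors.
"""


class VentriflowError(Exception):
    """Base class for all ventriflow errors."""


class FormatError(VentriflowError):
    """On-disk data does not match the declared layout (shape/dtype mismatch)."""


class ConfigError(VentriflowError):
    """Invalid or incomplete configuration / sidecar metadata."""


class GeometryError(VentriflowError):
    """Physical frames of reference do not overlap or are inconsistent."""


class DomainError(VentriflowError):
    """A scalar parameter is outside its mathematical domain."""


class DataError(VentriflowError):
    """Input values violate a data precondition (negative magnitudes, empty mask...)."""


class DegenerateInputError(VentriflowError):
    """Input is formally valid but the requested quantity is undefined on it."""


class SizeError(VentriflowError):
    """Input too small for the operation (filter support, sample size...)."""


class AlignmentError(VentriflowError):
    """Two inputs that must share a grid or timing do not."""


class PhantomSpecError(VentriflowError):
    """Phantom specification is internally inconsistent."""


class StageError(VentriflowError):
    """Pipeline stage failure; carries the stage name."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
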