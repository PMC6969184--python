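"""Exception hierarchy.

Every contract violation in the package raises a named subclass of
:class:`UpsweepError` so callers can distinguish failure modes without
string matching.
"""


class UpsweepError(Exception):
    """Base class for all package errors."""


class AudioFileError(UpsweepError):
    """Missing or unreadable audio file."""


class UnsupportedEncodingError(AudioFileError):
    """WAV encoding the reader does not handle."""


class ChannelError(AudioFileError):
    """Requested channel does not exist in the file."""


class SelectionTableError(UpsweepError):
    """Malformed selection table; carries the offending row when known."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class ClipContractError(UpsweepError):
    """Audio clip violates the duration/sample-rate contract of a feature op."""


class AnnotationOutsideStreamError(UpsweepError):
    """Annotation does not intersect the stream it is being cut from."""


class InsufficientCallFreeTimeError(UpsweepError):
    """Not enough annotation-free audio to place the requested windows.

    ``achievable`` reports how many windows could be placed instead.
    """

    def __init__(self, requested: int, achievable: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"cannot place {requested} call-free windows; achievable: {achievable}"
        )


class UntrainedScorerError(UpsweepError):
    """Scorer used before it was fitted."""


class ArchitectureError(UpsweepError):
    """Unknown architecture name; message lists the registry."""


class SingleClassError(UpsweepError):
    """Training data contains only one class."""


class NonFiniteLossError(UpsweepError):
    """Loss became NaN/Inf during training; carries the epoch index."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")


class StreamTooShortError(UpsweepError):
    """Stream shorter than one analysis window."""


class EvaluationError(UpsweepError):
    """Invalid evaluation input (no annotations, non-positive hours, ...)."""


class SceneConfigError(UpsweepError):
    """Unsatisfiable synthetic-scene configuration."""


class LeakageError(UpsweepError):
    """Same stream appears in both the training and the test split."""
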