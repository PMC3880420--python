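"""Exception hierarchy shared across the pipeline."""


class GardenSageError(Exception):
    """Base class for all errors raised by this package."""


class InvalidConfigError(GardenSageError):
    """A configuration value violates its contract."""


class WrongStateError(GardenSageError):
    """A count matrix is in the wrong raw/normalized state for an operation."""


class ZeroTotalLibraryError(GardenSageError):
    """A library column sums to zero and cannot be CPM-normalized."""

    def __init__(self, library_id: str):
        self.library_id = library_id
        super().__init__(f"library {library_id!r} has a total count of zero")


class MissingTagError(GardenSageError):
    """A tag referenced by a count matrix has no ground-truth record."""


class DesignError(GardenSageError):
    """A library cannot be mapped to an experimental section."""


class DegenerateVarianceError(GardenSageError):
    """A group has zero variance; Welch ANOVA is undefined."""


class InsufficientReplicatesError(GardenSageError):
    """Fewer than two replicate values in a group."""


class TooShortError(GardenSageError):
    """A query sequence is shorter than the configured n-mer length."""


class DataUnavailableError(GardenSageError):
    """A published dataset required for a computation is not distributable."""


class StageError(GardenSageError):
    """A pipeline stage failed; wraps the underlying cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
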