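"""Exception hierarchy shared across the pipeline stages."""


class EpilinkError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EpilinkError, ValueError):
    """An argument violates a stated precondition."""


class NoTissueError(EpilinkError):
    """A label mask contains no epithelial or stromal pixels."""


class UndefinedCorrelationError(EpilinkError):
    """Correlation requested on a constant vector."""


class CombinatorialExplosionError(EpilinkError):
    """Exhaustive permutation enumeration requested for n too large."""


class InsufficientCohortError(EpilinkError):
    """Fewer shared samples than the analysis requires."""


class EmptyResultError(EpilinkError):
    """An operation produced no testable records."""


class InvalidGroupingError(EpilinkError):
    """A two-group test received an empty or degenerate grouping."""


class DegenerateClusteringError(EpilinkError):
    """k-means produced an empty cluster after all restarts."""


class StageError(EpilinkError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
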