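"""Exception hierarchy shared across the pipeline stages."""


class DelforgeError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DelforgeError):
    """A structure string could not be parsed into a molecule."""


class EmptySetError(DelforgeError):
    """A filtering stage removed every candidate.

    Parameters
    ----------
    stage : str
        Name of the pipeline stage that emptied the set.
    """

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"no candidates survived stage '{stage}'")


class IncompatibleBuildingBlockError(DelforgeError):
    """Building block does not carry the functional group a transform needs."""


class AmbiguousBuildingBlockError(DelforgeError):
    """Building block carries more than one copy of the reacting group."""


class ContractViolationError(DelforgeError):
    """An operation was invoked outside its stated precondition."""


class ReactivityOrderError(ContractViolationError):
    """An aliphatic-site transform was attempted while the aromatic azide
    was still unreacted; the scaffold's reactivity hierarchy requires the
    aromatic site to be consumed first."""


class CapacityError(DelforgeError):
    """A generator was asked for more unique structures than its template
    space can provide."""

    def __init__(self, requested: int, capacity: int):
        self.requested = requested
        self.capacity = capacity
        super().__init__(
            f"requested {requested} unique structures but only ~{capacity} "
            f"are reachable from the configured template pools"
        )


class UndefinedCorrelationError(DelforgeError):
    """Pearson correlation is undefined (zero variance or too few points)."""


class GridMismatchError(DelforgeError):
    """Two density maps were compared but were not built on a shared grid."""
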