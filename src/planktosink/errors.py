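"""Exception hierarchy for planktosink.

Every error raised on purpose by the package derives from
:class:`PlanktosinkError`, so callers (and the CLI) can catch one base class.
"""


class PlanktosinkError(Exception):
    """Base class for all planktosink errors."""


class InvalidCompositionError(PlanktosinkError):
    """A molecular composition violates its invariants (e.g. all-zero volumes)."""


class DomainError(PlanktosinkError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class DecompositionUndefinedError(PlanktosinkError):
    """Taylor influence decomposition has a (near-)cancelling denominator."""


class NoChangeError(DecompositionUndefinedError):
    """Baseline and perturbed states are identical; nothing to attribute."""


class AttributionUndefinedError(PlanktosinkError):
    """Observed velocity change is zero; percent-explained is undefined."""


class EmptyPopulationError(PlanktosinkError):
    """A filtering step removed every cell from a sample."""


class PairingError(PlanktosinkError):
    """Samples that must share metadata (species/condition/replicate) do not."""


class InconsistentMeasurementError(PlanktosinkError):
    """Dual-fluid buoyant-mass measurements violate the forward model."""


class InsufficientDataError(PlanktosinkError):
    """Too few replicates or data points for the requested statistic."""


class ZeroVarianceError(PlanktosinkError):
    """A test statistic is undefined because the data have no variance."""


class ValidationError(PlanktosinkError):
    """Input table or configuration failed schema validation."""

    def __init__(self, message: str, rows: list | None = None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []
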