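"""Exception hierarchy shared across the package."""


class BnctkitError(Exception):
    """Base class for all package-specific errors."""


class InputDomainError(BnctkitError, ValueError):
    """An input violates a physical or statistical precondition."""


class InfeasiblePlanError(BnctkitError):
    """An irradiation plan cannot be realised within reactor limits.

    Carries ``required_power`` (kW) when the inverse dose solve exceeds
    the maximum reactor power.
    """

    def __init__(self, message: str, required_power: float | None = None):
        super().__init__(message)
        self.required_power = required_power


class DegenerateDesignError(BnctkitError, ValueError):
    """A regression design has no spread (e.g. all calibration points equal)."""


class NoObjectError(BnctkitError):
    """Segmentation produced an empty foreground."""


class UndefinedPerimeterError(BnctkitError):
    """Shape metrics requested for a degenerate (single-pixel) object."""


class GatingError(BnctkitError):
    """Flow-cytometry gating could not be derived (e.g. too few events)."""


class StageError(BnctkitError):
    """A pipeline stage failed; the bundle is partial."""
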