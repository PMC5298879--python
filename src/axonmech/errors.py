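"""Exception hierarchy for axonmech.

All domain errors derive from :class:`AxonMechError` so callers can catch
pipeline failures without masking programming errors.
"""


class AxonMechError(Exception):
    """Base class for all axonmech domain errors."""


class InvalidParameterError(AxonMechError, ValueError):
    """A physical parameter is outside its admissible range."""


class UnitError(InvalidParameterError):
    """A quantity appears to be in the wrong unit (e.g. kPa passed as Pa)."""


class DiscretizationError(InvalidParameterError):
    """Rod discretization too coarse for the requested geometry."""


class NumericalFailureError(AxonMechError):
    """The integrator produced non-finite forces.

    Carries the step index at which the failure occurred.
    """

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class InsufficientDataError(AxonMechError, ValueError):
    """Not enough samples/defects/coils to compute the requested statistic."""


class FitFailureError(AxonMechError):
    """A least-squares fit failed to converge or was degenerate."""


class LowSignalError(AxonMechError):
    """Signal amplitude below the noise floor; fit would be meaningless."""


class NonPhysicalFitError(AxonMechError):
    """A fit returned a value outside the physical branch (e.g. a <= 0)."""


class TopologyError(AxonMechError):
    """Input image/skeleton has the wrong topology (loop, multiple components)."""


class DegenerateGeometryError(AxonMechError):
    """Geometry is rank-deficient for the requested operation."""


class InvalidSizeError(AxonMechError, ValueError):
    """Image or array dimensions incompatible with the requested windows."""


class NoSignalError(AxonMechError):
    """All measurement windows were masked; nothing to analyze."""
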