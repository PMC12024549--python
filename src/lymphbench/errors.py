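"""Exception and warning hierarchy for lymphbench."""


class LymphBenchError(Exception):
    """Base class for all lymphbench errors."""


class InvalidGeometryError(LymphBenchError, ValueError):
    """Non-positive length, diameter, or viscosity."""


class InvalidMeasurementError(LymphBenchError, ValueError):
    """A measured value is physically impossible (e.g. outer diameter <= wall thickness)."""


class UndefinedResistanceError(LymphBenchError, ZeroDivisionError):
    """Resistance requested at zero flow (the 0/0 pressure step)."""


class EmptySeriesError(LymphBenchError, ValueError):
    """No usable (nonzero-flow) pressure steps remain."""


class SingularFitError(LymphBenchError, ValueError):
    """Linear fit is degenerate (all abscissae identical)."""


class CalibrationInconsistentError(LymphBenchError, ValueError):
    """Connector resistance came out negative: slope below the phantom's Poiseuille resistance."""


class InsufficientDataError(LymphBenchError, ValueError):
    """Fewer data points than free parameters (or than required by the operation)."""


class FitConvergenceError(LymphBenchError, RuntimeError):
    """Optimizer failed to converge. Carries the best parameters found so far."""

    def __init__(self, message: str, best_model=None, best_objective: float | None = None):
        super().__init__(message)
        self.best_model = best_model
        self.best_objective = best_objective


class InvalidModelError(LymphBenchError, ValueError):
    """Model evaluation requested outside its domain (e.g. non-positive flow denominator)."""


class NegativeValveResistanceWarning(UserWarning):
    """A decomposed valve resistance came out negative; kept as-is for fitting."""


class DroppedPointsWarning(UserWarning):
    """Data points were excluded from a fit (e.g. non-positive valve pressure gradients)."""
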