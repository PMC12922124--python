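"""Exception hierarchy for toxmix.

All domain errors derive from :class:`ToxmixError` so callers can catch one
type; subclasses mirror the failure modes of the analysis stages.
"""


class ToxmixError(ValueError):
    """Base class for all toxmix domain errors."""


class InsufficientDesignError(ToxmixError):
    """Too few usable concentrations (or observations) to fit the model."""


class DegenerateResponseError(ToxmixError):
    """Response carries no information (all dead / all alive / constant)."""


class InvalidConcentrationError(ToxmixError):
    """Concentration outside the model's domain (must be > 0)."""


class NonMonotoneError(ToxmixError):
    """Curve or input ordering inconsistent with a monotone dose-response."""


class DesignError(ToxmixError):
    """Inconsistent toxic-unit design specification."""


class SchemaError(ToxmixError):
    """Tabular input does not match the expected column schema."""


class ConvergenceError(ToxmixError):
    """Optimizer failed to converge from every start."""
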