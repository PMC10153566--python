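"""Exception hierarchy for panel validation and solver failures."""


class HealthDEAError(Exception):
    """Base class for all package errors."""


class PanelValidationError(HealthDEAError, ValueError):
    """A panel violates a structural invariant."""


class SchemaError(PanelValidationError):
    """A required column is missing or the schema itself is inconsistent."""


class BalanceError(PanelValidationError):
    """The panel is not a complete DMU x period grid."""


class PositivityError(PanelValidationError):
    """An input or output quantity is zero or negative."""


class UnknownPeriodError(PanelValidationError):
    """A requested period is not present in the panel."""


class SolverError(HealthDEAError, RuntimeError):
    """An LP or likelihood optimisation failed for a reason other than infeasibility."""
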