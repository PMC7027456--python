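"""Exception hierarchy for the techno-economic model."""


class PhytoTeaError(Exception):
    """Base class for all package errors."""


class FlowsheetValidationError(PhytoTeaError):
    """A stream or unit-operation specification violates its invariants."""


class ConfigurationError(PhytoTeaError):
    """A scenario configuration is malformed or references unknown entities."""


class SchedulingError(PhytoTeaError):
    """The requested batch schedule is infeasible (names the bottleneck)."""


class EconomicsError(PhytoTeaError):
    """A cost computation received invalid inputs (e.g. zero demand)."""
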