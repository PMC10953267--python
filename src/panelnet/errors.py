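"""Exception hierarchy shared across the pipeline stages."""


class PanelnetError(Exception):
    """Base class for all panelnet errors."""


class ConfigurationError(PanelnetError, ValueError):
    """A run configuration, scale definition, or column mapping is invalid."""


class DataError(PanelnetError, ValueError):
    """The input data violate a structural invariant (e.g. duplicate rows)."""


class EstimationError(PanelnetError, RuntimeError):
    """A statistical estimate could not be computed from the data given."""


class ConvergenceError(EstimationError):
    """An iterative solver failed to converge within its iteration cap."""


class ReliabilityError(EstimationError):
    """Internal-consistency reliability is undefined (zero total variance)."""
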