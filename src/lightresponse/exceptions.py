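"""Exception and warning hierarchy for :mod:`lightresponse`."""


class LightResponseError(Exception):
    """Base class for all package errors."""


class DomainError(LightResponseError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class InvalidParameterError(LightResponseError, ValueError):
    """A parameter set violates its model's invariants."""


class NoCompensationPointError(LightResponseError, ValueError):
    """The net curve never crosses zero (respiration exceeds attainable assimilation)."""


class InsufficientDataError(LightResponseError, ValueError):
    """Too few observations for the requested operation."""


class DegenerateVarianceError(LightResponseError, ValueError):
    """The observed values have zero variance, so SST-based statistics are undefined."""


class MissingColumnError(LightResponseError, KeyError):
    """A required column is absent from an input table."""


class PartitionWarning(UserWarning):
    """Diagnostic warning from electron-flow partitioning (e.g. negative J_O)."""


class SimulationWarning(UserWarning):
    """Diagnostic warning from the synthetic-data generator."""
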