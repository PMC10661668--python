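"""Exception hierarchy shared across stimchip modules."""


class StimchipError(Exception):
    """Base class for all package-specific errors."""


class DomainError(StimchipError, ValueError):
    """A physical parameter is outside its valid domain (e.g. sigma <= 0)."""


class TopologyError(StimchipError, ValueError):
    """Resistor network is not connected between the source terminals."""


class SolverError(StimchipError, RuntimeError):
    """The nodal-analysis linear system could not be solved."""


class InsufficientDataError(StimchipError, ValueError):
    """Too few samples for the requested analysis."""


class CapacityError(StimchipError, RuntimeError):
    """Rejection-sampling budget exhausted (cell packing infeasible)."""


class NormalizationError(StimchipError, ValueError):
    """A normalization denominator is zero or negative."""


class ClusteringError(StimchipError, ValueError):
    """Grouped analysis requires more clusters than were provided."""
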