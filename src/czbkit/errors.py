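"""Exception hierarchy shared across the package."""


class CzbError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(CzbError):
    """A coordinate file line could not be parsed (carries the line number)."""


class TopologyError(CzbError):
    """Models of a multi-model file (or ensemble members) disagree in topology."""


class SelectionError(CzbError):
    """An atom selection resolved to an empty or unusable atom set."""


class AlignmentError(CzbError):
    """Superposition impossible: too few atoms or degenerate geometry."""


class RestraintResolutionError(CzbError):
    """A restraint names an atom that does not exist on the topology."""


class ConnectivityError(CzbError):
    """An aliphatic hydrogen has no standard parent carbon."""


class ConfigError(CzbError):
    """Invalid run configuration."""


class ContractError(CzbError):
    """A documented precondition of an operation was violated."""


class GenerationError(CzbError):
    """The synthetic-data generator could not satisfy its own construction."""


class RadiusError(CzbError):
    """An element has no radius in the active radii set."""
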