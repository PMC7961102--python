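"""Exception hierarchy shared by all modules."""


class CofilsevError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CofilsevError):
    """Invalid configuration: unknown selection/rule names, bad parameters."""


class StructuralError(CofilsevError):
    """A structure lacks residues/atoms a selection or operation requires."""


class TopologyError(CofilsevError):
    """Filament topology violated: missing subunits, bad occupancy, aperiodic input."""


class FormatError(CofilsevError):
    """File-format problem on PDB read/write."""


class InputError(CofilsevError):
    """Mismatched or otherwise unusable operation inputs."""


class NumericalError(CofilsevError):
    """Degenerate geometry that defeats a numerical procedure."""


class GenerationError(CofilsevError):
    """The synthetic generator cannot realise the requested geometry."""


class DomainError(CofilsevError):
    """Operation applied to a subunit kind it is not defined for."""


class NoTransitionError(CofilsevError):
    """Profile is flat; no boundary transition to fit."""
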