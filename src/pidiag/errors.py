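"""Exception hierarchy.

Every error raised by the library derives from :class:`PidiagError`, so
callers (and the CLI) can map failures onto exit codes without catching
bare ``ValueError``.
"""


class PidiagError(Exception):
    """Base class for all pidiag errors."""


class ConfigError(PidiagError, ValueError):
    """Malformed or inconsistent configuration."""


class InvalidDesignError(PidiagError, ValueError):
    """A simulation design violates its invariants."""


class WrongValueKindError(PidiagError, TypeError):
    """An expression matrix of the wrong value kind was supplied."""


class AlignmentError(PidiagError, ValueError):
    """Gene or sample identifiers do not line up between inputs."""


class DomainError(PidiagError, ValueError):
    """A scalar argument is outside its mathematical domain."""


class DataError(PidiagError, ValueError):
    """Input data violate a precondition (missing metadata, bad layout)."""


class DegenerateGeneError(DataError):
    """A gene has no usable measurements (e.g. all zeros)."""


class DegenerateAnovaError(DataError):
    """Zero within-cell variance everywhere; the ANOVA F is undefined."""


class ConvergenceError(PidiagError, RuntimeError):
    """An iterative solver failed to converge."""


class NoMappableFeaturesError(PidiagError, ValueError):
    """No diagnostic feature survives the ortholog mapping."""
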