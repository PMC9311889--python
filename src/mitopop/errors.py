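"""Exception hierarchy shared across the package."""


class MitopopError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(MitopopError):
    """Ragged alignments, empty alignments, length mismatches."""


class AlphabetError(MitopopError):
    """Characters outside {A, C, G, T, -, N}."""


class PopmapError(MitopopError):
    """Sample/population bookkeeping failures."""


class UndefinedStatisticError(MitopopError):
    """A statistic is mathematically undefined for the given input (e.g. Hd at n < 2)."""


class SaturationError(MitopopError):
    """Distance correction breaks down (log of a non-positive argument)."""


class SimulationError(MitopopError):
    """Infeasible simulator configuration (e.g. site exhaustion)."""
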