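"""Exception hierarchy.

Errors are grouped so the command-line layer can map them to distinct exit
codes: configuration problems, data-format problems, and computation failures.
"""


class SoundnavError(Exception):
    """Base class for all package errors."""


class ConfigError(SoundnavError, ValueError):
    """Invalid configuration or arguments."""


class FormatError(SoundnavError, ValueError):
    """Malformed input file (session log, layout, mesh)."""


class GenerationError(SoundnavError, RuntimeError):
    """Course generation could not satisfy the placement constraints."""


class SimulationError(SoundnavError, RuntimeError):
    """Trial simulation infeasible (e.g. no traversable gap)."""


class RegistrationError(SoundnavError, RuntimeError):
    """Fiducial-based registration failed (degenerate orientation)."""


class DirectionError(SoundnavError, RuntimeError):
    """Travel direction undefined (no displacement above epsilon)."""


class GimbalError(SoundnavError, RuntimeError):
    """Device forward axis too close to vertical for a planar heading."""


class IncompleteTrialError(SoundnavError, RuntimeError):
    """Trajectory never crossed the finish threshold.

    Carries the protocol's time-cap semantics so callers can report the
    trial with a capped elapsed time instead of dropping it.
    """

    def __init__(self, message: str, time_cap: float = 180.0):
        super().__init__(message)
        self.time_cap = time_cap
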