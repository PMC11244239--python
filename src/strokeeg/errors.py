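"""Exception and warning types shared across the package."""


class StrokeEegError(Exception):
    """Base class for all strokeeg errors."""


class ParameterError(StrokeEegError, ValueError):
    """An operation was called with invalid parameters."""


class ConfigurationError(StrokeEegError, ValueError):
    """A configuration object is internally inconsistent."""


class UnrecoverableDataError(StrokeEegError):
    """The data cannot be repaired (e.g. every channel marked bad)."""


class EmptyResultWarning(UserWarning):
    """An operation produced an empty result (e.g. all epochs rejected)."""


class DegeneratePhaseWarning(UserWarning):
    """Instantaneous phase requested for a (near-)constant signal."""


class UndefinedSampleEntropyWarning(UserWarning):
    """No template matches at length m+1; sample entropy capped."""
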