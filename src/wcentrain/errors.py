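"""Exception hierarchy for the wcentrain package."""


class WcentrainError(Exception):
    """Base class for all package-specific errors."""


class ModelDomainError(WcentrainError, ValueError):
    """An argument lies outside the mathematical domain of the model."""


class IntegrationError(WcentrainError, RuntimeError):
    """Numerical integration produced a non-finite state.

    Attributes
    ----------
    time : float
        Simulation time (seconds) at which the failure was detected.
    """

    def __init__(self, time: float):
        self.time = time
        super().__init__(f"integration produced a non-finite state at t = {time:.4f} s")


class NoOscillationError(WcentrainError, RuntimeError):
    """The trajectory does not exhibit a usable sustained oscillation."""


class ProtocolError(WcentrainError, RuntimeError):
    """The drive protocol could not be realized (e.g. no admissible switch time)."""


class InsufficientDataError(WcentrainError, ValueError):
    """A segment is too short for the requested spectral analysis."""


class EmptySpectrumError(WcentrainError, ValueError):
    """No spectral peaks were found where at least one is required."""


class UndefinedPhaseError(WcentrainError, RuntimeError):
    """A final phase difference was requested for a run that is not 1:1 entrained."""


class ConfigError(WcentrainError, ValueError):
    """A configuration file failed validation."""
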