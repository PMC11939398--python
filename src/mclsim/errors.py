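"""Exception types raised by the simulator and experiment harness."""


class MclError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MclError):
    """Inconsistent or illegal parameter combination."""


class ConfigFileError(MclError):
    """A configuration file failed to parse or validate."""


class DegenerateChamberError(MclError):
    """A Windkessel chamber has been flooded (non-positive air column)."""


class IntegrationError(MclError):
    """NaN/Inf appeared in the ODE state during integration."""


class InstabilityError(MclError):
    """The trajectory diverged (volume exceeded the instability bound)."""


class InfeasibleTargetError(MclError):
    """A trim/calibration target lies outside the achievable range."""

    def __init__(self, message: str, achieved: float | None = None):
        super().__init__(message)
        self.achieved = achieved


class InsufficientDataError(MclError):
    """Too few observations for the requested summary/statistic."""


class CollinearityError(MclError):
    """Rank-deficient design matrix in a regression."""

    def __init__(self, message: str, columns: list[int] | None = None):
        super().__init__(message)
        self.columns = columns or []
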