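"""Exception hierarchy shared across the pipeline."""


class NursetagError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NursetagError):
    """A file does not conform to the tag-record or event-log format."""


class TimingError(NursetagError):
    """Timestamps are not uniform at the declared sampling rate."""


class ValidationError(NursetagError):
    """A domain object violates one of its invariants."""


class RateError(NursetagError):
    """Requested resampling ratio is not realisable."""


class CalibrationError(NursetagError):
    """Frame-correction calibration window is unusable."""


class ParameterError(NursetagError):
    """An analysis parameter is out of its admissible range."""


class ConfigError(NursetagError):
    """A simulation configuration is internally inconsistent."""


class InfeasibleSamplingError(NursetagError):
    """Requested number of disjoint segments exceeds feasible capacity."""

    def __init__(self, requested: int, achievable: int, message: str | None = None):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            message
            or f"cannot place {requested} disjoint segments; "
            f"achievable maximum is {achievable}"
        )
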