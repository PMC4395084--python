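"""Exception hierarchy used across the package."""


class MfwarnError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MfwarnError, ValueError):
    """A parameter is outside its admissible range."""


class ScaleFeasibilityError(MfwarnError, ValueError):
    """The signal is too short for the requested dyadic scale range.

    Carries ``max_feasible`` — the largest octave the signal supports.
    """

    def __init__(self, message: str, max_feasible: int):
        super().__init__(message)
        self.max_feasible = max_feasible


class StructuralError(MfwarnError, ValueError):
    """An intermediate container is missing required content."""


class TrainingError(MfwarnError, ValueError):
    """Training data cannot support fitting (e.g. a class is empty)."""


class ConfigurationError(MfwarnError, ValueError):
    """A run configuration is inconsistent with the data."""


class LeakageError(ConfigurationError):
    """Training and testing data overlap."""


class FormatError(MfwarnError, ValueError):
    """An on-disk file does not match the expected format."""
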