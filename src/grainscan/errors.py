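"""Exception hierarchy for the grainscan pipeline."""


class GrainScanError(Exception):
    """Base class for all grainscan errors."""


class InvalidInputError(GrainScanError, ValueError):
    """An argument violates an operation's precondition."""


class InvalidParameterError(GrainScanError, ValueError):
    """A tuning parameter is outside its valid domain."""


class CalibrationError(GrainScanError):
    """No usable reference object could be found in a calibration image."""


class DegenerateKernelError(GrainScanError):
    """A detected contour has zero extent on some axis."""


class SceneTooCrowdedError(GrainScanError):
    """Non-overlapping kernel placement failed after bounded retries."""


class NotFittedError(GrainScanError, RuntimeError):
    """A model was used before training."""


class ConfigError(GrainScanError):
    """A rice-type configuration is inconsistent or references missing files."""
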