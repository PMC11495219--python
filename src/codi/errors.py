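"""Exception hierarchy for spectral-fingerprint handling and experiment protocols."""


class CodiError(Exception):
    """Base class for all package-specific errors."""


class SpectraFormatError(CodiError):
    """File structure is not the expected dialect (e.g. missing axis header)."""


class SpectraParseError(CodiError):
    """A cell could not be parsed as a number; message names the row."""


class SpectraValidationError(CodiError):
    """Values violate a dataset invariant (NaN/Inf, shape mismatch)."""


class AxisMismatchError(CodiError):
    """Two datasets do not share a spectral axis (count or values differ)."""


class DegenerateRowError(CodiError):
    """A row cannot be normalized (zero Euclidean norm)."""


class InsufficientCalibrationError(CodiError):
    """Too few calibration measurements to characterize a variability source."""


class PairingError(CodiError):
    """Paired calibration sets have mismatched measurement counts."""


class InsufficientDataError(CodiError):
    """Not enough rows/points for the requested statistic."""


class DegenerateTaskError(CodiError):
    """Classification task has fewer than two classes."""


class InsufficientClassError(CodiError):
    """A class has too few training rows for the requested model."""


class ParameterError(CodiError):
    """A parameter is outside its valid domain."""


class LabelDomainError(CodiError):
    """Test labels fall outside the trained label set."""


class ProtocolError(CodiError):
    """Scenario does not satisfy an experiment's entry conditions."""


class LeakageError(CodiError):
    """Calibration subjects overlap train/test subjects."""
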