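"""Exception hierarchy for clamap."""


class ClamapError(Exception):
    """Base class for all clamap errors."""


class ProtocolMismatchError(ClamapError):
    """A trace or request does not match the light-stimulation protocol."""


class CalibrationError(ClamapError):
    """The effect table or its calibration fixture is incomplete or invalid."""


class DataIntegrityError(ClamapError):
    """Non-finite samples or missing required metadata."""


class ConfigurationError(ClamapError):
    """Analysis windows or inference settings are inconsistent."""


class IncompleteRecordError(ClamapError):
    """A cell record is missing traces for one or more protocol intensities."""


class LabelingError(ClamapError):
    """A cell carries an unknown input/output region or subtype label."""


class UnclassifiableError(ClamapError):
    """A step response with no spikes cannot be assigned a subtype."""


class DegenerateStatisticError(ClamapError):
    """A test statistic is undefined (zero variance, n too small)."""
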