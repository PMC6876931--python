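"""Exception hierarchy for the digitization pipeline."""


class EcgDigitizeError(Exception):
    """Base class for all pipeline errors."""


class InputError(EcgDigitizeError):
    """Unreadable, corrupt, or structurally invalid input."""


class ParameterError(EcgDigitizeError):
    """A parameter outside its documented valid range."""


class DetectionError(EcgDigitizeError):
    """Region-of-interest detection failed or disagrees with the layout."""


class ExtractionError(EcgDigitizeError):
    """Trace extraction could not produce a path."""


class CalibrationError(EcgDigitizeError):
    """Scale pulse could not be located or measured."""


class FiducialError(EcgDigitizeError):
    """PQRST fiducials or intervals are undefined for the signal."""


class SpecError(EcgDigitizeError):
    """Invalid synthetic-page specification."""
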