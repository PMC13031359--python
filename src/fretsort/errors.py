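"""Exceptions shared across the package."""


class FretsortError(Exception):
    """Base class for all package-specific errors."""


class DegenerateSignalError(FretsortError):
    """Background subtraction left a non-positive median in a required channel.

    Usually means the biosensor was not expressed or the wrong sample was
    provided as signal/background.
    """


class CalibrationError(FretsortError):
    """The spectral calibration could not be determined from the given samples."""


class UnidentifiableFitError(FretsortError):
    """The data do not constrain the model parameters (e.g. a flat titration)."""
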