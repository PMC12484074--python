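"""Exception hierarchy for stresskit.

Every error raised deliberately by the package derives from
:class:`StressKitError`, so callers can catch one type at pipeline level.
"""


class StressKitError(Exception):
    """Base class for all stresskit errors."""


class SpectralFormatError(StressKitError):
    """The file is not a recognisable spectral-library CSV."""


class SpectralParseError(StressKitError):
    """A cell could not be parsed; the message names the row and column."""


class SpectralValidationError(StressKitError):
    """Parsed data violates a library invariant (e.g. negative reflectance)."""


class BandNotFoundError(StressKitError):
    """No band within tolerance of the requested wavelength."""


class ParameterError(StressKitError):
    """An operation was called with out-of-contract parameters."""


class InsufficientDataError(StressKitError):
    """Too few samples for the requested statistic."""


class AlignmentError(StressKitError):
    """Two objects that must share a band grid do not."""


class ContractError(StressKitError):
    """An object does not satisfy the interface contract it was used under."""


class StratificationError(StressKitError):
    """A class has too few samples to be split across train/val/test."""


class DivergenceError(StressKitError):
    """Training produced a non-finite loss."""
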