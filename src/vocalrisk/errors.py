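"""Exception hierarchy for the vocalrisk pipeline.

Every stage raises a subclass of :class:`VocalRiskError` so callers can
distinguish bad inputs (format, duration, periodicity) from configuration
mistakes and numerical failures.
"""


class VocalRiskError(Exception):
    """Base class for all package errors."""


class AudioFormatError(VocalRiskError):
    """Unreadable, non-PCM, or otherwise malformed audio input."""


class TooShortError(VocalRiskError):
    """Recording or clip shorter than the minimum analyzable duration."""

    def __init__(self, message: str, duration_s: float | None = None):
        super().__init__(message)
        self.duration_s = duration_s


class NormalizationError(VocalRiskError):
    """Amplitude normalization is undefined (e.g. all-zero signal)."""


class InsufficientPeriodicityError(VocalRiskError):
    """Too few glottal cycles detected for cycle-level measures."""


class DataIntegrityError(VocalRiskError):
    """Internally inconsistent data (e.g. non-positive cycle periods)."""


class ConfigurationError(VocalRiskError):
    """Invalid analysis configuration (unknown feature names, bad grids...)."""


class DivergenceError(VocalRiskError):
    """Model optimization diverged (NaN loss); try a smaller learning rate."""
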