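"""Exception hierarchy for the pelvimon pipeline."""


class PelvimonError(Exception):
    """Base class for all pelvimon errors."""


class DomainError(PelvimonError, ValueError):
    """A physical quantity is outside its admissible domain."""


class ValidationError(PelvimonError, ValueError):
    """A protocol, configuration or data structure is internally inconsistent."""


class ResolutionError(PelvimonError, ValueError):
    """The sampling rate is too low to resolve the requested waveform."""


class FilterDesignError(PelvimonError, ValueError):
    """A filter cutoff is incompatible with the sampling rate."""


class CalibrationError(PelvimonError, RuntimeError):
    """Phase calibration failed (no detectable carrier)."""


class NormalizationError(PelvimonError, RuntimeError):
    """The baseline level is below the noise floor (bad electrode contact)."""


class ConfigError(PelvimonError, ValueError):
    """A run configuration contains unknown or invalid keys."""
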