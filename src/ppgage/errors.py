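"""Exception hierarchy for the PPG analysis pipeline.

Every stage raises a subclass of :class:`PPGAgeError` so callers can catch
pipeline problems without masking programming errors.
"""


class PPGAgeError(Exception):
    """Base class for all errors raised by ppgage."""


class ParameterError(PPGAgeError, ValueError):
    """An argument or configuration value is outside its valid domain."""


class SegmentationError(PPGAgeError):
    """Pulse-boundary detection failed (too few beats, flat signal, ...)."""


class FiducialDetectionError(PPGAgeError):
    """A required SDPPG wave (a-e) could not be located."""

    def __init__(self, missing_wave: str, message: str | None = None):
        self.missing_wave = missing_wave
        super().__init__(message or f"{missing_wave}-wave not found before pulse end")


class DegeneratePulseError(PPGAgeError):
    """The pulse is degenerate for the requested feature (e.g. a-wave amplitude 0)."""


class TrainingError(PPGAgeError):
    """Model training diverged or produced non-finite loss."""


class PipelineError(PPGAgeError):
    """Failure inside a multi-stage run, annotated with the stage that failed."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
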