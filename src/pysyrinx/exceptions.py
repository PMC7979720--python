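"""Exception hierarchy for the pysyrinx pipeline."""


class PysyrinxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PysyrinxError):
    """A file does not have the expected layout (e.g. a channel is missing)."""


class IntegrityError(PysyrinxError):
    """A file is structurally readable but internally inconsistent."""


class ConfigError(PysyrinxError):
    """Invalid or unknown configuration value."""


class SegmentationError(PysyrinxError):
    """Ramp segmentation disagrees with the stated protocol."""

    def __init__(self, message, candidates=None):
        super().__init__(message)
        self.candidates = candidates or []
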