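"""Package exception hierarchy."""


class OkamutError(Exception):
    """Base class for all package-specific errors."""


class MalformedAlignmentError(OkamutError):
    """Rows of a multiple sequence alignment have unequal lengths."""


class ConfigurationError(OkamutError):
    """Missing reference row, taxon mismatch, or other bad configuration."""


class DesignError(OkamutError):
    """A synthetic genome/cohort design is infeasible as specified."""


class WindowExceededError(OkamutError):
    """An event window exceeds the short-event scope of the fitter."""
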