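"""Exception types shared across the package."""


class SpikefieldError(Exception):
    """Base class for all package-specific errors."""


class WindowMismatchError(SpikefieldError, ValueError):
    """Two windows that must be congruent (same length / sampling / channel
    count) are not."""


class DegenerateScaleError(SpikefieldError, ValueError):
    """A data-driven scale (kernel size, correlation) cannot be estimated
    because the inputs carry no variability."""


class RecordingFormatError(SpikefieldError, ValueError):
    """A recording file on disk is malformed.  The message names the file and,
    where applicable, the 1-based line number of the offending row."""


class EmptyModelError(SpikefieldError, ValueError):
    """An operation that requires a trained (non-empty) kernel model was
    called on a model with no dictionary centers."""
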