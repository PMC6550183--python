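"""Exception types shared across the pipeline."""


class PillPipeError(Exception):
    """Base class for all pillpipe errors."""


class InvalidArgument(PillPipeError, ValueError):
    """An argument violates an operation's precondition."""


class NoPillFound(PillPipeError):
    """Reference-image keying found no foreground pixel."""


class PlacementFailed(PillPipeError):
    """Scene composition could not place a pill without overlap."""


class ValidationError(PillPipeError, ValueError):
    """Input data failed validation (e.g. missing NDC, unknown class)."""
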