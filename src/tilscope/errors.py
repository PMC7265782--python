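"""Exception hierarchy shared across the pipeline stages."""


class TilscopeError(Exception):
    """Base class for all tilscope errors."""


class SpecValidationError(TilscopeError, ValueError):
    """A generator/config spec violates its invariants."""


class NoTissueError(TilscopeError):
    """A slide (or FOV crop) contains no detectable tissue."""


class TrainingDivergedError(TilscopeError):
    """Training produced a non-finite loss."""


class FormatError(TilscopeError, ValueError):
    """A serialized artifact failed validation on load."""
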