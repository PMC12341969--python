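"""Exception hierarchy shared across fluxmark."""


class FluxmarkError(Exception):
    """Base class for all fluxmark errors."""


class ModelParseError(FluxmarkError):
    """A model file could not be parsed; message names the offending element."""


class ModelValidationError(FluxmarkError):
    """A model violates a structural invariant (duplicate ids, bad bounds...)."""


class GprParseError(FluxmarkError):
    """A gene-protein-reaction rule is syntactically invalid."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class InfeasibleModelError(FluxmarkError):
    """An LP stage reported an infeasible (or unbounded) model."""


class PipelineError(FluxmarkError):
    """A pipeline stage failed; message names the stage and the cause."""
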