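"""Exception hierarchy for gemrank."""


class GemrankError(Exception):
    """Base class for all gemrank errors."""


class ValidationError(GemrankError):
    """Input data violates a documented invariant."""


class FormatError(GemrankError):
    """A file could not be parsed in the declared format."""


class GprParseError(FormatError):
    """A gene-protein-reaction rule is syntactically malformed."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class InfeasibleError(GemrankError):
    """The LP has no feasible steady-state flux distribution."""


class UnboundedError(GemrankError):
    """The LP objective is unbounded above."""
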