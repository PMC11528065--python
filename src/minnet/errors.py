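"""Exception hierarchy shared across the package."""


class MinnetError(Exception):
    """Base class for all package-specific errors."""


class ModelFormatError(MinnetError):
    """A model file could not be parsed in the requested format."""


class ConfigurationError(MinnetError):
    """The model or run configuration is ambiguous or incomplete."""


class ValidationError(MinnetError):
    """A model, medium, or state violates a structural invariant."""


class GprParseError(MinnetError):
    """A gene-reaction rule string is malformed.

    Carries ``position``: the 0-based character offset at which parsing failed.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class ContractError(MinnetError):
    """An operation was called with arguments violating its contract."""


class InfeasibleError(MinnetError):
    """The underlying optimisation problem has no feasible point."""


class SolverError(MinnetError):
    """The numerical solver failed for reasons other than infeasibility."""
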