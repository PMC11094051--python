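"""Exception and warning types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates an operation's preconditions."""


class EstimationError(RuntimeError):
    """A model fit could not be completed (degenerate data, no candidates)."""


class InfeasibleError(EstimationError):
    """A requested sample cannot be drawn from the available data."""


class SchemaError(ValueError):
    """An input file or config does not match the documented schema."""


class UndefinedResultWarning(UserWarning):
    """A statistic is undefined for the given inputs (e.g. zero variance)."""
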