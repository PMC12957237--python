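"""Exception types shared across the pipeline stages."""


class InvalidArgumentError(ValueError):
    """An argument violates a precondition (shape, range, or consistency)."""


class FormatError(ValueError):
    """A fixture file is malformed; the message names the offending field."""


class FlaggedChannelError(ValueError):
    """Degenerate channels make a fit impossible.

    Carries the offending channel indices in :attr:`channels`.
    """

    def __init__(self, channels, message=None):
        self.channels = list(channels)
        super().__init__(
            message or f"zero-variance channel(s): {self.channels}"
        )


class NumericalError(ArithmeticError):
    """A matrix failed a numerical requirement (e.g. not positive definite)."""


class UndefinedStatisticError(ArithmeticError):
    """The requested statistic is undefined for this input (degenerate case)."""
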