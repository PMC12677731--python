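"""Exception types shared across the pipeline."""


class DailyGaitError(Exception):
    """Base class for all package errors."""


class FormatError(DailyGaitError):
    """Input file does not conform to the documented CSV dialect."""


class SamplingError(DailyGaitError):
    """Time column is not uniformly sampled within tolerance."""


class EmptyInputError(DailyGaitError):
    """An operation received an empty signal or table."""


class DegenerateBoutError(DailyGaitError):
    """Bout step times are degenerate (e.g. duplicate identical times)."""


class ProtocolError(DailyGaitError):
    """A synthetic protocol is internally inconsistent or unreachable."""


class DegenerateTableError(DailyGaitError):
    """A contingency table has a zero margin."""


class FitError(DailyGaitError):
    """Model fitting failed; carries diagnostics when available."""

    def __init__(self, message, best=None, diagnostics=None):
        super().__init__(message)
        self.best = best
        self.diagnostics = diagnostics or {}
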