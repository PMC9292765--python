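"""Exception hierarchy shared by all marmot modules."""


class MarmotError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(MarmotError):
    """A user-supplied configuration value is invalid or inconsistent."""


class DataError(MarmotError):
    """The input data violate a precondition (missing values, bad labels...)."""


class OracleInfeasibleError(MarmotError):
    """Exact enumeration of linear extensions would exceed the requested cap."""


class EmptyOverlapError(MarmotError):
    """Every average-rank row was discarded: no common support across treatments.

    Carries per-treatment diagnostics in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
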