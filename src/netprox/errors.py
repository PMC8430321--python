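"""Exception types shared across the package."""


class NetproxError(Exception):
    """Base class for all package-specific errors."""


class ParseError(NetproxError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class MissingNodeError(NetproxError):
    """A node required for the operation is absent from the graph."""


class ConsistencyError(NetproxError):
    """Cross-table references do not line up (e.g. a pair names an unknown compound)."""


class SamplingError(NetproxError):
    """A degree-matched sample could not be drawn (bin exhausted)."""


class DegenerateNullError(NetproxError):
    """The null distance distribution has zero spread, so no Z-score exists.

    Carries the observed distance and the null mean so callers can still report them.
    """

    def __init__(self, d_c: float, mu: float):
        super().__init__(
            f"degenerate null: every replicate produced the same distance "
            f"(d_c={d_c:g}, mu={mu:g}); Z-score undefined"
        )
        self.d_c = d_c
        self.mu = mu


class GenerationError(NetproxError):
    """A synthetic-data request is infeasible for the given graph/parameters."""
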