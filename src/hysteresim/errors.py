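"""Exception types shared across the toolkit."""


class HysteresimError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(HysteresimError, ValueError):
    """A scalar parameter or parameter set violates its constraints."""


class RangeError(HysteresimError, ValueError):
    """An evaluation time falls outside the span of the supplied curve."""


class ConfigurationError(HysteresimError, ValueError):
    """A configuration is internally inconsistent or infeasible."""


class ParseError(HysteresimError, ValueError):
    """A delimited-text input file could not be parsed.

    Carries the offending 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
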