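"""Exception hierarchy for the quantification pipeline."""


class RamanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RamanError):
    """A file violates the documented plain-text format or a type invariant."""


class ParseError(FormatError):
    """A cell could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ArgumentError(RamanError, ValueError):
    """Invalid argument to a processing operation."""


class FitError(RamanError):
    """Nonlinear fit failed to converge; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float | None = None):
        self.best_residual = best_residual
        super().__init__(message)


class CalibrationError(RamanError):
    """Wavenumber calibration failed (no reference band found)."""


class QuantificationError(RamanError):
    """Quantification impossible (e.g. internal-standard band absent)."""
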