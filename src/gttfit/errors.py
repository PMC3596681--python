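"""Exception hierarchy for gttfit.

Numerical failures (integration blow-up, singular normal equations,
divergence) are kept distinct from input/validation errors so callers --
in particular the command-line interface -- can map them to different
exit codes.
"""


class GTTFitError(Exception):
    """Base class for all gttfit errors."""


class ValidationError(GTTFitError, ValueError):
    """Invalid user input: bad parameter values, malformed series, bad units."""


class ParseError(ValidationError):
    """A CSV file failed validation; ``line`` is the 1-based file line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class NumericalError(GTTFitError, ArithmeticError):
    """Base class for failures of the numerical machinery."""


class IntegrationBlowUp(NumericalError):
    """The state became non-finite during integration; ``time`` records where."""

    def __init__(self, time: float):
        self.time = time
        super().__init__(f"integration blow-up: non-finite state at t = {time:g} min")


class SingularNormalEquations(NumericalError):
    """Gauss-Newton normal matrix J'J is singular or numerically rank-deficient."""


class Diverged(NumericalError):
    """An iterative fit increased its objective for too many consecutive steps."""
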