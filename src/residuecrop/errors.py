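"""Exception hierarchy shared across the package.

Validation problems (bad tables, bad configs, domain violations) and
numerical failures are kept distinct so the command-line layer can map
them to different exit codes (2 and 3 respectively).
"""

from __future__ import annotations


class ResidueCropError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ResidueCropError):
    """Invalid input data, configuration or argument domain.

    ``violations`` lists every individual problem found, so a caller can
    report all of them at once rather than one per run.
    """

    def __init__(self, message: str, violations: list[str] | None = None):
        self.violations = list(violations or [])
        if self.violations:
            message = message + "\n  - " + "\n  - ".join(self.violations)
        super().__init__(message)


class TooFewPointsError(ValidationError):
    """Not enough usable observations to fit or pair."""


class NumericalError(ResidueCropError):
    """A numerical routine failed (mass loss, non-convergence, ...)."""


class NonConvergenceError(NumericalError):
    """Nonlinear fit did not converge.

    Carries the log-linear fallback estimate so the caller can still
    inspect an approximate answer.
    """

    def __init__(self, message: str, fallback=None):
        super().__init__(message)
        self.fallback = fallback
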