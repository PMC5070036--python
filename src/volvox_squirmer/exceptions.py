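"""Exception types shared across the package."""


class VolvoxSquirmerError(Exception):
    """Base class for all package errors."""


class SingularWavenumberError(VolvoxSquirmerError, ValueError):
    """Raised when the metachronal wavenumber is an integer (or within the
    guard band of one), where the travelling-wave projection formulas are
    singular."""


class InvalidModeError(VolvoxSquirmerError, ValueError):
    """Raised for mode indices outside the validity of a basis function
    (e.g. the tangential basis V_n starts at n = 1)."""


class ConvergenceError(VolvoxSquirmerError, RuntimeError):
    """Raised when a truncation-convergence requirement is not met.

    Carries the convergence trace (list of (N, value) pairs) in ``trace``.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []
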