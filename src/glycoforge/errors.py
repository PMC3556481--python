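"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`GlycoforgeError`, so callers (and the CLI) can distinguish
user-input problems from computation failures.
"""


class GlycoforgeError(Exception):
    """Base class for all glycoforge errors."""


class ValidationError(GlycoforgeError, ValueError):
    """Invalid user input: bad residue, out-of-range position, malformed file."""


class EpitopeSyntaxError(ValidationError):
    """Malformed annotated-epitope string (unbalanced parentheses etc.)."""


class AlphabetLookupError(GlycoforgeError, LookupError):
    """A glycan state name is not defined in the active alphabet."""


class SizeGuardError(GlycoforgeError, ValueError):
    """Requested enumeration exceeds the configured combinatorial bound."""


class ConvergenceError(GlycoforgeError, RuntimeError):
    """A nonlinear fit failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FitQualityError(GlycoforgeError, RuntimeError):
    """Data are incompatible with the model (flat or non-monotone curve)."""

    def __init__(self, message: str, r_squared: float | None = None):
        super().__init__(message)
        self.r_squared = r_squared
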