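"""Exception hierarchy.

Simulation failures that the benchmark harness tabulates (no steady state,
negative states, Newton non-convergence, numerical errors) are *statuses*,
not exceptions; only genuine usage/modelling errors raise.
"""


class EqsensError(Exception):
    """Base class for all package errors."""


class SchemaError(EqsensError):
    """Malformed model document or table (unknown symbol, missing column, ...)."""


class ValidationError(EqsensError):
    """Structurally valid input that violates a constraint (bounds, scales, ...)."""


class TailoredMethodInapplicable(EqsensError):
    """Raised when a steady-state linear solve is attempted with a rank-deficient
    (or numerically near-singular) Jacobian. Callers fall back to integration
    or propagate the condition as a structured failure category."""


class SimulationError(EqsensError):
    """Internal signal carrying a failure category and the phase it occurred in.

    Converted into structured statuses at the objective/benchmark boundary.
    """

    def __init__(self, category: str, phase: str, message: str = ""):
        self.category = category
        self.phase = phase
        super().__init__(message or f"{category} during {phase}")
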