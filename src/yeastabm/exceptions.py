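"""Exception hierarchy.

``ConfigurationError`` maps to CLI exit code 1, the runtime aborts
(:class:`StepSizeError`, :class:`InvariantViolation`) to exit code 2.
"""


class YeastABMError(Exception):
    """Base class for all package errors."""


class ConfigurationError(YeastABMError):
    """Invalid parameter value, unit, or configuration file."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class StepSizeError(YeastABMError):
    """Explicit-Euler step drove a biomass compartment negative (dt too large)."""


class InvariantViolation(YeastABMError):
    """A model invariant (mass conservation, non-negativity) was broken."""
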