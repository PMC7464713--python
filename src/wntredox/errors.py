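"""Exception types used across the package."""


class WntRedoxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WntRedoxError, ValueError):
    """Invalid model configuration: missing parameter, unknown flag, bad value."""


class ScopeError(WntRedoxError, KeyError):
    """A gene/species outside the intracellular model scope was referenced."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class InvariantViolation(WntRedoxError, ValueError):
    """A state violated a structural invariant (e.g. negative copy number)."""


class SimulationError(WntRedoxError, RuntimeError):
    """Numerical failure inside a simulation or steady-state search."""
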