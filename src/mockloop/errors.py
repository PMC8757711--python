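"""Exception hierarchy for the loop digital twin.

All errors raised on bad *values* derive from :class:`DomainError` (a
``ValueError``) so callers can catch one base; structural problems
(mismatched grids, empty inputs) raise :class:`ShapeError`.
"""


class MockLoopError(Exception):
    """Base class for all package errors."""


class DomainError(MockLoopError, ValueError):
    """A physical quantity is outside its valid domain (e.g. diameter <= 0)."""


class ShapeError(MockLoopError, ValueError):
    """Structurally incompatible inputs: mismatched grids, empty series."""


class ConfigurationError(MockLoopError, ValueError):
    """Invalid configuration or parameter set."""


class RangeError(DomainError):
    """A requested operating point is outside the hardware's reachable range."""


class DegenerateDesignError(MockLoopError, ValueError):
    """A regression design with no spread in the predictor."""


class StabilityError(MockLoopError, ValueError):
    """Integration step too coarse for the system's time constant."""


class ConvergenceError(MockLoopError, RuntimeError):
    """A simulation did not reach the requested steady regime."""
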