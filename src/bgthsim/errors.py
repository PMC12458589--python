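"""Exception hierarchy shared across the package."""


class BGTHSimError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(BGTHSimError, ValueError):
    """A scalar parameter is outside its admissible range."""


class ValidationError(BGTHSimError, ValueError):
    """A matrix or structured object violates a structural invariant."""


class InvalidEdgeError(ValidationError):
    """A connectome edge has a non-positive length, bad index, or self-loop."""


class DuplicateEdgeError(ValidationError):
    """The same undirected node pair appears twice in an edge list."""


class FormatError(BGTHSimError, ValueError):
    """A file on disk does not have the expected columns or layout."""


class StateError(BGTHSimError, ValueError):
    """A dynamical state contains non-finite or inadmissible values."""


class IntegrationError(BGTHSimError, RuntimeError):
    """A derivative became non-finite during time stepping."""

    def __init__(self, message, component=None, step=None):
        super().__init__(message)
        self.component = component
        self.step = step


class ResolutionError(BGTHSimError, ValueError):
    """A measurement grid is too coarse for the feature being measured."""


class ComparisonError(BGTHSimError, ValueError):
    """Simulation results are not commensurable (e.g. mismatched durations)."""


class FixtureError(BGTHSimError, ValueError):
    """A synthetic test trace was requested with inconsistent geometry."""
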