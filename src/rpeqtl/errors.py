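"""Exception hierarchy shared across the package."""


class RpeqtlError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RpeqtlError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ConsistencyError(RpeqtlError, ValueError):
    """Inputs reference entities that do not exist or disagree."""


class InsufficientDataError(RpeqtlError, ValueError):
    """Not enough observations to run the requested computation."""


class SingularModelError(RpeqtlError, ArithmeticError):
    """The model system is degenerate (no unique solution)."""


class InfeasibleInputsError(RpeqtlError, ValueError):
    """Inputs admit a unique solution, but it falls outside the valid domain."""


class InvalidTopologyError(RpeqtlError, ValueError):
    """A junction cluster does not have the required shared splice sites."""
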