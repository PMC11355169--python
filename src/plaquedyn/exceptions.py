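"""Exception hierarchy shared by all plaquedyn modules."""


class PlaquedynError(Exception):
    """Base class for all plaquedyn errors."""


class DomainError(PlaquedynError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class EvaluationError(PlaquedynError, ValueError):
    """A user-supplied function produced a non-finite or invalid value."""


class SimulationError(PlaquedynError, RuntimeError):
    """A simulated trajectory left its admissible state space."""

    def __init__(self, message: str, visit: int | None = None):
        super().__init__(message)
        self.visit = visit


class AnalysisError(PlaquedynError, RuntimeError):
    """A numerical analysis routine failed to bracket or converge."""


class ModelError(PlaquedynError, ValueError):
    """A model violates a structural requirement (e.g. ergodicity)."""


class DegenerateModelError(ModelError):
    """A transformation produced a degenerate model (e.g. an all-zero row)."""


class ClassificationError(PlaquedynError, ValueError):
    """A risk classification could not be made from the available estimates."""


class ConfigError(PlaquedynError, ValueError):
    """A configuration file is malformed or contains unknown keys."""


class ContractError(PlaquedynError, ValueError):
    """Data handed to an I/O routine violates its documented contract."""
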