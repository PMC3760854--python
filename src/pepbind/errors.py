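"""Exception hierarchy shared across the package."""


class PepBindError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PepBindError, ValueError):
    """A file or text block does not conform to its expected format."""


class ChainNotFoundError(PepBindError, KeyError):
    """A requested chain id is absent from a structure (or has no atoms)."""


class BoundsError(PepBindError, ValueError):
    """A coordinate, span or window parameter is out of range."""


class ValidationError(PepBindError, ValueError):
    """An input value violates a documented precondition."""


class EngineError(PepBindError, RuntimeError):
    """An external or mock docking engine failed or returned no poses."""


class EvaluationError(PepBindError, ValueError):
    """ROC/AUC evaluation is undefined for the given inputs."""


class ConfigurationError(PepBindError, ValueError):
    """A run or training configuration is inconsistent or infeasible."""
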