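"""Exception hierarchy shared across the package.

Every error raised by photonet derives from :class:`PhotonetError`, so callers
(including the CLI) can map error classes onto exit codes.
"""


class PhotonetError(Exception):
    """Base class for all photonet errors."""


class ConfigurationError(PhotonetError, ValueError):
    """An invalid generator, network, swarm, or pipeline configuration."""


class DomainError(PhotonetError, ValueError):
    """An input value outside the physical/mathematical domain of an operation."""


class SchemaError(PhotonetError, ValueError):
    """A dataset file that does not conform to the CSV schema."""


class DegenerateFeatureError(PhotonetError, ValueError):
    """A constant feature that cannot be normalized or correlated."""


class UndefinedCorrelationError(PhotonetError, ValueError):
    """Pearson correlation undefined (constant series or too few samples)."""


class DimensionError(PhotonetError, ValueError):
    """Array shape or length inconsistent with the declared architecture."""


class DivergenceError(PhotonetError, ArithmeticError):
    """Non-finite loss or fitness encountered during optimization."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch
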