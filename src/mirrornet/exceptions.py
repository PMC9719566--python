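"""Exception hierarchy used across the package."""


class MirrornetError(Exception):
    """Base class for package errors."""


class InvalidSpecError(MirrornetError, ValueError):
    """A stimulus/model/run specification violates its contract."""


class InvalidDataError(MirrornetError, ValueError):
    """Input data violate a precondition (e.g. empty family, single class)."""


class UndefinedStatisticError(MirrornetError, ArithmeticError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class StageDependencyError(MirrornetError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""
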