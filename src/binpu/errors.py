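"""Exception hierarchy shared across the package.

Every error raised on a user-facing path derives from :class:`BinPUError`
so callers (and the CLI) can distinguish input problems from genuine bugs.
"""


class BinPUError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(BinPUError):
    """A file does not conform to its declared dialect."""


class ConflictError(BinPUError):
    """The same (compound, protein) pair appears with contradictory labels."""


class ConsistencyError(BinPUError):
    """Cross-references between tables and entities do not resolve."""


class ParameterError(BinPUError):
    """A configuration value is outside its valid range."""


class ContractViolationError(BinPUError):
    """A pluggable backbone broke its fit/predict contract."""


class FeaturizationError(BinPUError):
    """An entity string cannot be featurized (too short / empty)."""


class DegenerateTrainingError(BinPUError):
    """Training data contains a single class."""


class NotFittedError(BinPUError):
    """predict was called on an unfitted backbone."""


class UndefinedMetricError(BinPUError):
    """A metric has no defined value (e.g. SCR with zero spies)."""


class CalibrationError(BinPUError):
    """The synthetic-world bias cannot be calibrated to the target prevalence."""
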