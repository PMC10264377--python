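"""Named error types raised across the pipeline stages."""


class HistomilError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HistomilError, ValueError):
    """Invalid configuration values (proportions, sizes, allocation)."""


class UndefinedLabelError(HistomilError, ValueError):
    """A bulk label cannot be derived (e.g. a patient without tumor tiles)."""


class DegenerateDataError(HistomilError, ValueError):
    """Input data carry no usable variation (identical values, single class)."""


class ContractViolationError(HistomilError, ValueError):
    """A pluggable component returned output violating its declared contract."""


class ShapeMismatchError(HistomilError, ValueError):
    """Paired containers (features vs grid/manifest) disagree in length."""


class TrainingDivergedError(HistomilError, RuntimeError):
    """Training aborted on a non-finite loss."""
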