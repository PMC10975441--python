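"""Exception hierarchy for the hsimoist pipeline.

Every stage raises a subclass of :class:`HsiMoistError`, so callers can catch
pipeline failures without masking programming errors.
"""


class HsiMoistError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(HsiMoistError):
    """A configuration value violates its invariant; names the offending field."""


class CalibrationError(HsiMoistError):
    """Reflectance correction impossible (white - dark <= 0 somewhere)."""


class RangeError(HsiMoistError):
    """A wavelength window retains no bands."""


class SegmentationError(HsiMoistError):
    """Seed segmentation produced no foreground regions."""


class DegenerateSpectrumError(HsiMoistError):
    """A per-spectrum operation hit a degenerate row (zero sd, zero slope)."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DegenerateInputError(HsiMoistError):
    """All samples identical: no distance structure to split on."""


class CapacityError(HsiMoistError):
    """Scene synthesis could not place the requested number of seeds."""


class SchemeError(HsiMoistError):
    """A cross-validation scheme is infeasible for the sample count."""


class RankError(HsiMoistError):
    """Requested components exceed the achievable rank."""


class ContractError(HsiMoistError):
    """Axis/shape mismatch between pipeline stages."""


class UndefinedStatisticError(HsiMoistError):
    """A statistic is undefined for the given input (e.g. constant actual)."""
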