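"""Exception hierarchy for the day-factor pipeline."""


class DayFactorError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DayFactorError):
    """A file does not follow the expected CSV/YAML schema."""


class ValidationError(DayFactorError):
    """Data violate a structural invariant (non-positive magnitude, bad shape...)."""


class GridMismatchError(ValidationError):
    """Frequency grids differ across days or channels of one dataset."""


class DegenerateInputError(DayFactorError):
    """The computation is undefined for this input (zero range, zero variance...)."""


class UndefinedMetricError(DegenerateInputError):
    """A metric is undefined (zero-variance segment, zero signal range)."""
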