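"""Exception hierarchy shared across the package."""


class ContestLearnError(Exception):
    """Base class for all package errors."""


class BoundsError(ContestLearnError, ValueError):
    """An action (or other quantity) lies outside its admissible range."""


class CalibrationError(ContestLearnError, ValueError):
    """Payoff calibration conditions are inconsistent or rank deficient."""


class ConfigError(ContestLearnError, ValueError):
    """An agent spec, mixture or run configuration is invalid."""


class StateError(ContestLearnError, ValueError):
    """A history is too short (or otherwise unusable) for the requested rule."""


class SchemaError(ContestLearnError, ValueError):
    """A dataset file does not have the expected columns."""


class ParseError(ContestLearnError, ValueError):
    """A dataset file has malformed or out-of-bounds values."""


class EstimationError(ContestLearnError, ValueError):
    """A regression design is rank deficient or otherwise unfit."""


class TestError(ContestLearnError, ValueError):
    """A statistical test was asked of a degenerate sample."""
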