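"""Exception hierarchy for the cogtrend pipeline.

Every stage raises a subclass of :class:`CogtrendError` so callers can
catch pipeline failures without masking programming errors.
"""


class CogtrendError(Exception):
    """Base class for all cogtrend errors."""


class InvalidBenchmarkError(CogtrendError, ValueError):
    """Benchmark dispersion is non-positive or the benchmark row is missing."""


class MissingDataError(CogtrendError, ValueError):
    """An operation received an empty collection where data is required."""


class InsufficientDataError(CogtrendError, ValueError):
    """Fewer than two usable observations inside a fitting window."""


class DegenerateDesignError(CogtrendError, ValueError):
    """All observations share one calendar year; the slope is unidentified."""


class AnchorMissingError(CogtrendError, KeyError):
    """No observed value at the requested anchor year."""


class InconsistentPeriodError(CogtrendError, ValueError):
    """Trend models from different fitting windows were mixed."""


class ExtrapolationError(CogtrendError, ValueError):
    """A year outside the share table's range was requested."""


class EmptyPopulationError(CogtrendError, ZeroDivisionError):
    """Population shares sum to zero; no weighted mean exists."""


class ConfigurationError(CogtrendError, ValueError):
    """Inconsistent run configuration (e.g. unknown baseline group)."""


class InvalidScenarioError(CogtrendError, ValueError):
    """A synthetic scenario violates its own invariants."""


class InvalidHorizonError(CogtrendError, ValueError):
    """A per-decade rate was requested over a non-positive horizon."""


class UnknownFixtureError(CogtrendError, KeyError):
    """Requested packaged fixture name does not exist."""


class UnpairedSurveyWarning(UserWarning):
    """A survey year could not be paired within the allowed gap."""
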