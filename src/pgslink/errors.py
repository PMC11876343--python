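"""Exception hierarchy shared across pipeline stages."""


class PgslinkError(Exception):
    """Base class for all package errors."""


class ConfigError(PgslinkError, ValueError):
    """Invalid simulation or pipeline configuration."""


class NoOverlapError(PgslinkError):
    """No shared variants between a weight set / summary stats and genotypes."""


class CollinearityError(PgslinkError):
    """Rank-deficient design matrix; carries the offending column names."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"collinear design columns: {self.columns}")


class InsufficientInstrumentsError(PgslinkError):
    """Fewer instruments than the estimator requires."""


class InsufficientOverlapError(PgslinkError):
    """Fewer than two shared variants between colocalization regions."""


class InsufficientDataError(PgslinkError):
    """Too few rows/pairs/events for the requested analysis."""


class DegenerateOutcomeError(PgslinkError):
    """Outcome is constant or otherwise unusable."""


class NoEventsError(PgslinkError):
    """Survival data contain zero events."""


class EmptyCohortError(PgslinkError):
    """Cohort has no rows after filtering."""
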