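"""Exception hierarchy for the MR pipeline."""


class MRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRError):
    """A column map, config file or parameter combination is invalid."""


class NoRecordsError(MRError):
    """An input table contained no parseable summary-statistic rows."""


class HarmonizationError(MRError):
    """Exposure/outcome records cannot be harmonized as requested."""


class ClumpingError(MRError):
    """LD clumping cannot proceed (missing positions or LD entries)."""


class EstimationError(MRError):
    """A causal estimator cannot produce a valid estimate."""

    def __init__(self, message: str, last_iterate: float | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate
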