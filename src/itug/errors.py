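"""Exception hierarchy for the itug package."""


class ItugError(Exception):
    """Base class for all package-specific errors."""


class LogParseError(ItugError):
    """A sensor log line could not be parsed."""


class IntegrityError(ItugError):
    """A recording violates a structural invariant (e.g. non-monotone time)."""


class InsufficientDataError(ItugError):
    """Too few samples for the requested operation."""


class ConfigurationError(ItugError):
    """An invalid configuration value (bad axis map, unknown key, ...)."""


class NoActivityError(ItugError):
    """No active movement blocks were found in a session recording."""


class BaselineError(ItugError):
    """No quiescent baseline available for transition detection."""


class SegmentationError(ItugError):
    """A repetition could not be segmented into the expected phases."""

    def __init__(self, message: str, n_turns: int | None = None):
        super().__init__(message)
        self.n_turns = n_turns


class FeatureError(ItugError):
    """Feature extraction failed (too many missing values, bad interval)."""


class SchemaError(ItugError):
    """Mismatched feature names / column layout between related objects."""


class PreprocessingError(ItugError):
    """Predictor matrix cannot be preprocessed (zero-variance column, NaN)."""


class PairingError(ItugError):
    """Two cross-validation results cannot be compared pairwise."""


class HarnessError(ItugError):
    """The Monte-Carlo validation harness failed (too many skipped iterations)."""
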