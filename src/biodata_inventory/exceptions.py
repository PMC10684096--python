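"""Exception hierarchy for the inventory pipeline."""


class InventoryError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(InventoryError):
    """Bad or missing user-supplied configuration (query file, config values)."""


class RetrievalError(InventoryError):
    """Literature-API retrieval failed after bounded retries."""

    def __init__(self, message: str, last_status: int | None = None):
        super().__init__(message)
        self.last_status = last_status


class InferenceError(InventoryError):
    """A model backend failed while classifying or tagging."""


class NormalizationError(InventoryError):
    """A string could not be normalized into a URL comparison key."""


class ValidationError(InventoryError):
    """A review file or label file failed strict validation."""


class EnrichmentError(InventoryError):
    """A metadata/enrichment client failed after retries."""


class UndefinedMetricError(InventoryError):
    """A metric denominator is zero; the metric is undefined, not silently 0."""
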