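"""Exception hierarchy shared across the pipeline stages."""


class PartWholeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PartWholeError, ValueError):
    """An out-of-range or inconsistent configuration field; names the field."""


class StructuralError(PartWholeError, ValueError):
    """Mismatched shapes, missing runs/conditions, or inconsistent datasets."""


class DomainError(PartWholeError, ValueError):
    """A scalar argument outside its mathematical domain (e.g. |r| > 1)."""


class DegenerateDataError(PartWholeError, ValueError):
    """Zero-variance or otherwise degenerate data where a statistic is undefined."""
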