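"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """A configuration value is inconsistent with the schema or another setting."""


class CalibrationError(RuntimeError):
    """Intercept search failed to reach the target outcome prevalence."""


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. a single-class label set)."""
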