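"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration value is invalid; the message names the offending field."""


class InputDataError(ValueError):
    """Input data violate a structural precondition (dimensions, ranges, missingness)."""


class DesignError(ValueError):
    """The regression design is unusable (rank deficiency, single-sex interaction, ...)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""
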