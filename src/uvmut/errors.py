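"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A reference annotation, layout or protocol configuration is invalid."""


class DataError(ValueError):
    """Input data violate a pipeline precondition (e.g. empty pileup)."""


class EmptyPileupError(DataError):
    """Raised when frequencies are requested with no qualified full-length products."""
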