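"""Exception types shared across the pipeline."""


class PaleolbgError(Exception):
    """Base class for package errors."""


class ConfigurationError(PaleolbgError):
    """A configuration problem (missing column mapping, bad quorum, ...)."""


class ValidationError(PaleolbgError):
    """Input data violates a structural invariant."""
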