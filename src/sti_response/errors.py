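"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """An invalid configuration value or combination."""


class DataError(ValueError):
    """Input data violates a precondition (empty mask, single class, ...)."""


class CohortIOError(IOError):
    """A cohort file is missing or unreadable; message names the file."""
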