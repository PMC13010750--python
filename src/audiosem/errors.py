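"""Exception hierarchy."""


class AudiosemError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AudiosemError, ValueError):
    """Invalid configuration values (proportions, bands, grids...)."""


class MissingDataError(AudiosemError, ValueError):
    """A required audiometric value is absent from a record."""


class SchemaError(AudiosemError, ValueError):
    """A table lacks required columns or contains duplicate identifiers."""


class SequencingError(AudiosemError, RuntimeError):
    """An operation was invoked before its upstream labels were inferred."""
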