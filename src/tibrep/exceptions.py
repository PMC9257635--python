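class TibrepError(Exception):
    """Base class for errors raised by tibrep."""


class FormatError(TibrepError):
    """An input file does not conform to its declared dialect."""


class ConfigError(TibrepError):
    """A configuration value is invalid or inconsistent."""


class AnalysisError(TibrepError):
    """An analysis step cannot proceed on the given data."""
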