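"""Exception hierarchy for the pipeline."""


class ExanovaError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(ExanovaError):
    """A configuration value is invalid; the message names the offending field."""


class ParseError(ExanovaError):
    """A tabular input file is malformed; the message carries row/column coordinates."""


class DesignError(ExanovaError):
    """The study design violates a structural requirement (grouping, Pre samples, balance)."""
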