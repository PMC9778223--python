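"""Exception hierarchy for the kneemon package."""


class KneemonError(Exception):
    """Base class for all kneemon errors."""


class ConfigurationError(KneemonError, ValueError):
    """A configuration value is invalid or an unknown key was supplied."""


class DataQualityError(KneemonError, ValueError):
    """Input data violates a physical plausibility assumption."""


class ParseError(KneemonError, ValueError):
    """A CSV/JSON input file could not be parsed; names the offending
    column/key and, where available, the line number."""
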