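"""Exception hierarchy for clasp."""


class ClaspError(Exception):
    """Base class for all clasp errors."""


class ConfigError(ClaspError):
    """A configuration value (column mapping, threshold, ...) is invalid."""


class ParseError(ClaspError):
    """An input file could not be parsed; the message points at the row."""


class InputError(ClaspError):
    """A value passed to an operation violates its preconditions."""


class ModelError(ClaspError):
    """A compartment model is malformed or referenced inconsistently."""
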