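"""Exception hierarchy shared across the toolkit."""


class MgomicsError(Exception):
    """Base class for all toolkit errors."""


class ParseError(MgomicsError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(MgomicsError):
    """An input violated a structural contract (ids, signs, shapes)."""


class ParameterError(MgomicsError):
    """A user-supplied parameter is out of its legal range."""
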