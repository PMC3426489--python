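"""Exception hierarchy shared by all giena modules."""


class GienaError(Exception):
    """Base class for all errors raised by giena."""


class ParseError(GienaError):
    """A file could not be parsed; the message names the file and line."""


class ValidationError(GienaError):
    """Inputs parsed but violate an invariant (duplicate genes, bad labels, ...)."""
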