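"""Exception hierarchy shared across the pipeline."""


class HerbNetPharmError(Exception):
    """Base class for all package errors."""


class FormatError(HerbNetPharmError):
    """An input file does not match its documented schema."""


class ValidationError(HerbNetPharmError):
    """Input parses but violates a contract (duplicate ids, missing keys...)."""
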