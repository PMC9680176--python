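"""Exception hierarchy shared by all misset modules."""


class MissetError(Exception):
    """Base class for all errors raised by misset."""


class ParseError(MissetError):
    """Raised when a delimited input file cannot be parsed (empty file,
    ragged rows, ...)."""


class ConfigError(MissetError):
    """Raised for invalid policies, group definitions or synthetic-data
    configurations (unknown field names, malformed probability vectors...)."""


class SelectionError(MissetError, KeyError):
    """Raised when an explicitly requested intersection key is not present
    in the table it is being selected from."""


class DomainError(MissetError, ValueError):
    """Raised when a computation is requested outside its domain
    (entropy of all-zero counts, explanation of an empty selection)."""
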