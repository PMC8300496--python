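"""Exception hierarchy shared across the package."""


class CausaltextError(Exception):
    """Base class for all package errors."""


class InputError(CausaltextError):
    """A required input file is missing or unreadable."""


class EncodingError(InputError):
    """Input bytes are not valid UTF-8; message names the byte offset."""


class SchemaError(InputError):
    """A tabular input lacks a required column."""


class RISParseError(InputError):
    """A RIS bibliographic file is malformed; message names the record."""


class UniquenessError(CausaltextError):
    """Duplicate document identifiers in one corpus."""


class ConfigurationError(CausaltextError):
    """A backend, model or pipeline configuration problem."""


class ValidationError(CausaltextError):
    """A concept map, template spec or config value violates its invariants."""


class FocalNodeError(CausaltextError, LookupError):
    """Requested ego-network focal concept is not a node of the network."""
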