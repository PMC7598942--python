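"""Exception hierarchy used across the package."""


class SitelearnError(Exception):
    """Base class for all package errors."""


class SchemaError(SitelearnError):
    """A required column is absent or feature names disagree."""


class ValidationError(SitelearnError):
    """Input violates a table or configuration invariant."""


class ParseError(SitelearnError):
    """A cell could not be parsed as the declared type."""


class ContractError(SitelearnError):
    """An operation was called outside its precondition."""


class EmptySubgroupError(SitelearnError):
    """A contrast produced an empty class after filtering."""
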