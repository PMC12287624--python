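"""Exception hierarchy shared across the package."""


class ForagevarError(Exception):
    """Base class for all package errors."""


class SchemaError(ForagevarError):
    """Input table does not have the expected columns or categorical values."""


class ValidationError(ForagevarError):
    """Input table has the right shape but violates an invariant."""


class EmptySiteError(ForagevarError):
    """A site has no species with chemistry, so no weighted mean is defined."""


class InsufficientDataError(ForagevarError):
    """Too few sites/species for the requested model or decomposition."""
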