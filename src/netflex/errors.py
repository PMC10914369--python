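"""Exception types shared across the package."""


class NetflexError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NetflexError, ValueError):
    """Input violates the expected schema (missing column, overlapping
    consumer/resource namespaces, unparseable weight, ...)."""


class EmptyInputError(NetflexError, ValueError):
    """An operation received an empty table, series or network where a
    nonempty one is required."""
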