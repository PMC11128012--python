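"""Exception hierarchy shared across the package."""


class ElapmcError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ElapmcError, ValueError):
    """Input data violates a structural invariant (bad voxel label, ratio out of range...)."""


class SchemaError(ElapmcError, ValueError):
    """A table or model file is missing a required column/field."""


class DomainError(ElapmcError, ValueError):
    """A mathematically undefined request (zero denominator, empty class...)."""


class ConfigError(ElapmcError, ValueError):
    """An invalid configuration value (bag sizes, optimizer budget...)."""


class VersionError(ElapmcError, ValueError):
    """A serialized model was written by an incompatible format version."""
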