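"""Exception and warning types shared across the package."""


class SafbdgError(Exception):
    """Base class for all package errors."""


class SchemaError(SafbdgError):
    """An input table violates its documented schema."""


class PairingError(SafbdgError):
    """The 1:1 case-control pairing structure is broken."""

    def __init__(self, message, pair_ids=()):
        super().__init__(message)
        self.pair_ids = tuple(pair_ids)


class MappingError(SafbdgError):
    """The food-group mapping configuration is invalid or incomplete."""


class DomainError(SafbdgError, ValueError):
    """A numeric argument lies outside its scientific domain."""


class ConvergenceError(SafbdgError):
    """A model fit failed to converge or is non-identifiable."""


class SeparationError(ConvergenceError):
    """The likelihood has no finite maximum (separated data)."""


class DegenerateCutpointWarning(UserWarning):
    """A tertile cut-point pair collapsed to a single value."""


class UnmappedItemWarning(UserWarning):
    """An intake item is not covered by the food-group mapping."""
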