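"""Exception types shared across the package."""


class ThermogaitError(Exception):
    """Base class for package errors."""


class DomainError(ThermogaitError, ValueError):
    """An input lies outside the physical domain of a model (names the field)."""


class RangeError(ThermogaitError, ValueError):
    """A value lies outside a supported numeric range."""


class IdentifiabilityError(ThermogaitError, ValueError):
    """A fit or inversion is not identifiable from the given data."""


class SchemaError(ThermogaitError, ValueError):
    """A file does not match the documented schema (column, unit or type)."""
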