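"""Exception hierarchy shared across the package."""


class SeedScreenError(Exception):
    """Base class for all seedscreen errors."""


class InvalidMeasurementError(SeedScreenError):
    """A fluorescence measurement violates a precondition (e.g. peak mean <= 0)."""


class InsufficientDataError(SeedScreenError):
    """Too few events / rows to perform the requested operation."""


class ContractError(SeedScreenError):
    """An input violates a documented contract (off-grid level, bad count, ...)."""


class SchemaError(SeedScreenError):
    """A delimited-text table is missing required columns or has malformed rows."""
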