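"""Exception hierarchy for community data validation."""


class PollinetError(Exception):
    """Base class for all package-specific errors."""


class DimensionMismatchError(PollinetError):
    """Interaction matrix shape disagrees with the species lists."""


class UnknownSpeciesError(PollinetError):
    """A row/column identifier is missing from the species table."""


class DuplicateSpeciesError(PollinetError):
    """A species identifier occurs more than once."""


class NegativeCountError(PollinetError):
    """An interaction count is negative."""


class InfeasibleConfigError(PollinetError):
    """A generator configuration cannot be realized."""
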