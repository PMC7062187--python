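"""Exception hierarchy shared across the package."""


class MitoscreenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MitoscreenError):
    """A table is missing required columns or has malformed values."""


class ConsistencyError(MitoscreenError):
    """Data contradicts the declared plate layout or registry."""


class PlateLookupError(MitoscreenError, KeyError):
    """Unknown plate, replicate, well or parameter."""


class InsufficientReplicationError(MitoscreenError):
    """An operation needs at least two replicates and got fewer."""


class EmptyInputError(MitoscreenError):
    """All values missing where at least one finite value is required."""


class FitError(MitoscreenError):
    """A model fit could not be carried out (rank deficiency, one class...)."""


class CapacityError(MitoscreenError):
    """A simulation request exceeds the physical capacity of the plates."""


class DegenerateModelError(MitoscreenError):
    """A fitted model collapsed and cannot support the requested inference."""


class PlacementError(MitoscreenError):
    """Synthetic nuclei could not be placed without overlap."""
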