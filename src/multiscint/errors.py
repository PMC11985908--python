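"""Exception hierarchy shared across the package."""


class MultiscintError(Exception):
    """Base class for all package-specific errors."""


class RangeError(MultiscintError, ValueError):
    """A coordinate (energy, depth, angle) lies outside its admissible range."""


class ValidationError(MultiscintError, ValueError):
    """An input object violates one of its declared invariants."""


class DegenerateInputError(MultiscintError, ValueError):
    """Input is formally valid but leads to an ill-defined quantity
    (e.g. a totally transparent stack whose absorption density cannot
    be normalized)."""
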