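"""Exception hierarchy.

All package errors derive from :class:`KinnError` so callers can catch one
type; each also derives from the closest builtin so idiomatic ``except
ValueError`` code keeps working.
"""


class KinnError(Exception):
    """Base class for all kinn errors."""


class SpecificationError(KinnError, ValueError):
    """A model or scheme specification is incomplete or inconsistent."""


class DomainError(KinnError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class StructuralError(KinnError, ValueError):
    """A graph or array has the wrong structure (connectivity, shape)."""


class DegenerateSchemeError(KinnError, ArithmeticError):
    """The kinetic scheme admits no well-defined steady state."""


class EncodingError(KinnError, ValueError):
    """A sequence or alignment cannot be encoded."""


class DataError(KinnError, ValueError):
    """A dataset violates a contract (labels, columns, classes)."""
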