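"""Exception types shared across the package."""


class BeltlinkError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(BeltlinkError):
    """Raised for non-positive lengths, out-of-range segments and similar."""


class FormatError(BeltlinkError):
    """Raised when an input table or file lacks required structure."""


class CoordinateError(BeltlinkError):
    """Raised when a residue or atom cannot be located in a structure."""


class RestraintError(BeltlinkError):
    """Raised when a restraint references something the structures lack."""


class GenerationError(BeltlinkError):
    """Raised when a synthetic-data generator cannot honour its arguments."""
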