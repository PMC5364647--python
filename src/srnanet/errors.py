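"""Exception hierarchy.

Usage errors (bad flags) are handled by the CLI layer; everything raised
here is a data or validation problem and maps to CLI exit code 2.
"""


class SrnanetError(Exception):
    """Base class for all package errors."""


class MissingNodeError(SrnanetError):
    """An interaction references a node id absent from the network."""


class BipartitenessError(SrnanetError):
    """An edge would link two sRNAs or two mRNAs."""


class RegionError(SrnanetError):
    """A sequence interval is malformed or out of bounds."""


class DuplicateInteractionError(SrnanetError):
    """An interaction with the same endpoints and regions already exists."""


class ParseError(SrnanetError):
    """A document or table could not be parsed; message carries context."""


class ValidationError(SrnanetError):
    """An object violates a structural invariant."""


class RegistryError(SrnanetError):
    """An unknown operation name was requested from the pipeline registry."""
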