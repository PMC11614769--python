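"""Exception hierarchy.

Every error raised by the package derives from :class:`EphyError`, so callers
can catch one base class at pipeline boundaries.
"""


class EphyError(Exception):
    """Base class for all package errors."""


class ValidationError(EphyError):
    """Container contents violate a structural invariant."""


class BoundsError(ValidationError):
    """A trial-definition row points outside the payload."""


class StateError(EphyError):
    """Operation requires state the object does not have (e.g. no trials)."""


class SelectionError(EphyError):
    """A selection emptied the dataset or referenced missing labels."""


class ParameterError(EphyError):
    """An analysis parameter is out of its valid range."""


class FormatError(EphyError):
    """On-disk payload and header disagree, or a file is malformed."""


class VersionError(FormatError):
    """Unknown on-disk format version."""


class IncompatibilityError(EphyError):
    """Two datasets cannot be combined (shape / trial-structure mismatch)."""


class EngineError(EphyError):
    """A trial kernel violated its contract or a compute run failed."""


class CapabilityError(EphyError):
    """The requested backend feature is not available on this platform."""


class ImportFormatError(EphyError):
    """A foreign file (NWB, plain HDF5, arrays) could not be interpreted."""
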