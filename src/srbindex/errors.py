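"""Exception hierarchy for the srbindex pipeline.

Every error raised by the library derives from :class:`SRBIndexError`, so
callers orchestrating many wells can catch one base class and attach well
context.
"""


class SRBIndexError(Exception):
    """Base class for all srbindex errors."""


class ImageInputError(SRBIndexError, ValueError):
    """An input image (or pair of images) violates a precondition."""


class DegenerateImageError(SRBIndexError):
    """The image admits no threshold (e.g. constant intensity)."""


class InsufficientDataError(SRBIndexError):
    """Too few particles / doses / clusters for the requested fit."""


class UndefinedIndexError(SRBIndexError):
    """The ratiometric index is undefined (no cells or no nuclear signal)."""


class MissingControlError(SRBIndexError):
    """A normalisation stratum lacks a control well."""


class PlateMapError(SRBIndexError, ValueError):
    """The plate map fails validation."""


class InternalConsistencyError(SRBIndexError):
    """Mask/labels and derived structures disagree; indicates a bug."""
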