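"""Exception hierarchy for the CVI pipeline.

Every stage raises a subclass of :class:`CviError` so the CLI can report a
stage-tagged message and a nonzero exit code without a traceback.
"""


class CviError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CviError):
    """Image file has the wrong dimensionality or is not a readable NIfTI."""


class HeaderError(CviError):
    """NIfTI header carries invalid geometry (e.g. non-positive voxel sizes)."""


class ConfigurationError(CviError):
    """Missing or inconsistent configuration (side label, units, paths)."""


class RegistrationError(CviError):
    """Registration could not be performed (no overlap, optimizer failure)."""


class DegenerateInputError(CviError):
    """Too little data to compute a robust statistic."""


class UndefinedIndexError(CviError):
    """A ratio is undefined because its denominator volume is zero."""
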