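"""Exception hierarchy for the PSF analysis pipeline."""


class PsfQcError(Exception):
    """Base class for all package errors."""


class FormatError(PsfQcError):
    """Input file is unreadable or not a recognised TIFF layout."""


class DimensionError(PsfQcError):
    """Stack shape violates the minimum z/y/x requirements."""


class CalibrationError(PsfQcError):
    """Invalid voxel calibration (non-positive sizes)."""


class PlacementError(PsfQcError):
    """Synthetic spot too close to the volume border for its 3-sigma support."""


class DegenerateInputError(PsfQcError):
    """Input has no contrast (e.g. all values identical) where contrast is required."""


class DomainError(PsfQcError):
    """Scalar argument outside its mathematical domain."""
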