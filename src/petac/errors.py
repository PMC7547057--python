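"""Exception types raised across the pipeline."""


class PetacError(ValueError):
    """Base class for pipeline validation errors."""


class UnitError(PetacError):
    """A volume carried the wrong unit tag for the requested operation."""


class GridMismatchError(PetacError):
    """Two volumes were combined without an exactly matching grid."""


class CompartmentError(PetacError):
    """A phantom compartment does not fit inside the simulation grid."""


class ProtocolError(PetacError):
    """A CT protocol is outside the calibrated range or otherwise invalid."""


class ROIError(PetacError):
    """A region of interest is invalid on the given volume."""
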