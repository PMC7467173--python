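"""Exception hierarchy for domfit."""


class DomfitError(Exception):
    """Base class for all domfit errors."""


class FormatError(DomfitError):
    """Malformed or unsupported input file."""


class GridMismatchError(DomfitError):
    """Operation requires maps on an identical grid."""


class DegenerateMapError(DomfitError):
    """Map is constant where variation is required."""


class EmptyOverlapError(DomfitError):
    """Maps (or map and model) share no spatial extent."""


class UndersamplingError(DomfitError):
    """Requested resolution is finer than the grid can represent."""


class EmptyMaskError(DomfitError):
    """Correlation mask contains no voxels."""


class EmptyDomainError(DomfitError):
    """Residue selection matched nothing."""


class InvalidRotationError(DomfitError):
    """Rotation matrix is not orthonormal with det +1."""


class PackingError(DomfitError):
    """Could not place synthetic domains without clashes."""


class MappingError(DomfitError):
    """A referenced chain/residue cannot be resolved in the model."""


class NoAxisError(DomfitError):
    """Two domains have coincident centroids; no slide axis exists."""
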