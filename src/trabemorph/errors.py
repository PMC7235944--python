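"""Exception types shared across the toolkit."""


class TrabemorphError(Exception):
    """Base class for all toolkit errors."""


class FormatError(TrabemorphError):
    """A file could not be read or written in the requested format."""


class UnsupportedGeometryError(TrabemorphError):
    """The volume geometry violates an assumption (e.g. anisotropic voxels)."""


class BoundsError(TrabemorphError):
    """A region request falls outside the volume."""


class GeometryError(TrabemorphError):
    """Phantom parameters are inconsistent with the requested dimensions."""


class PreconditionError(TrabemorphError):
    """An operation was called on input that violates its contract."""


class DegeneratePhaseError(TrabemorphError):
    """The evaluated phase (foreground or background) is empty or fully excluded."""


class NoInterfaceError(TrabemorphError):
    """A solid or empty volume has no bone/background interface."""


class FitError(TrabemorphError):
    """An ellipsoid/tensor fit failed (rank deficiency or non-positive-definite)."""


class InsufficientDataError(TrabemorphError):
    """Too few paired samples for the requested statistic."""
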