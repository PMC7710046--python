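"""Exception hierarchy for afmsim."""


class AFMSimError(Exception):
    """Base class for all afmsim errors."""


class PDBParseError(AFMSimError):
    """Raised when PDB input contains no usable coordinate records."""


class TrajectoryConsistencyError(AFMSimError):
    """Raised when trajectory frames disagree in atom count or element sequence."""


class UnknownElementError(AFMSimError, KeyError):
    """Raised when an element symbol is missing from the radius table and no
    default radius is configured."""


class CoordinateOverflowError(AFMSimError):
    """Raised when a coordinate does not fit the fixed 8.3 PDB column format."""


class ValidationError(AFMSimError, ValueError):
    """Raised on invalid parameters (non-orthonormal rotations, non-positive
    steps, out-of-domain tip geometry, ...)."""


class UndefinedCorrelationError(AFMSimError):
    """Raised when a correlation score is undefined (zero variance inside the
    region of interest, or too few pixels)."""
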