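"""Exception hierarchy for the toolkit."""


class RemorphError(Exception):
    """Base class for all toolkit errors."""


class EmptyMeshError(RemorphError):
    """Operation requires a non-empty mesh or cloud."""


class NotWatertightError(RemorphError):
    """Enclosed volume is undefined for open (non-watertight) surfaces."""


class InconsistentOrientationError(NotWatertightError):
    """Mesh is closed but faces have mixed winding; volume sign is ill-defined."""


class EmptySelectionError(RemorphError):
    """A selection region contained no geometry; adjust the region."""


class FormatError(RemorphError):
    """Malformed input file.

    Carries the 1-based line number where parsing failed, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ContourError(RemorphError):
    """A point cloud does not satisfy the stacked-contour-loop structure."""


class SliceError(RemorphError):
    """Slicing failed (bad plane coordinate, non-convergent cut search, ...)."""
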