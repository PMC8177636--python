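"""Exception hierarchy for nuctract."""


class NuctractError(Exception):
    """Base class for all package errors."""


class ContourError(NuctractError):
    """Invalid contour: too few points, duplicates, self-intersection, zero area."""


class ContourParseError(ContourError):
    """A contour file could not be parsed.  Carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DegenerateImageError(NuctractError):
    """Image has no intensity contrast (e.g. constant image for thresholding)."""


class NoObjectError(NuctractError):
    """Thresholded image contains no foreground object."""


class NotStarShapedError(NuctractError):
    """A ray from the remeshing origin crosses the boundary != 1 time."""

    def __init__(self, angle: float, n_hits: int):
        self.angle = angle
        self.n_hits = n_hits
        super().__init__(
            f"contour is not star-shaped about the requested origin: ray at "
            f"angle {angle:.6f} rad crosses the boundary {n_hits} times"
        )


class MeshError(NuctractError):
    """Evaluation mesh too coarse or inconsistent field sizes."""


class IncompressibilityError(NuctractError):
    """Strain trace does not vanish although the Poisson ratio is 0.5."""


class AnnealError(NuctractError):
    """Simulated-annealing failure (non-finite energy, bad configuration)."""
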