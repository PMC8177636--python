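"""Closed boundary polylines in physical units.

A :class:`Contour` stores the ordered vertices of a simple closed polygon in
micrometres.  Closure is implicit (the last vertex connects back to the
first) and the stored orientation is always anticlockwise, i.e. the signed
shoelace area is positive in a right-handed x-y frame (y up).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely.geometry

from .errors import ContourError

MIN_POINTS = 8

__all__ = ["Contour", "signed_area", "MIN_POINTS"]


def signed_area(points: np.ndarray) -> float:
    """Signed shoelace area of a closed polyline (positive = anticlockwise)."""
    x = points[:, 0]
    y = points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Contour:
    """Ordered, closed, simple, anticlockwise boundary polyline (μm).

    Parameters
    ----------
    points:
        ``(N, 2)`` array of vertices.  ``N >= 8``; no two consecutive
        vertices (including the wrap-around pair) may coincide.  A clockwise
        input is silently reversed so that the stored orientation is always
        anticlockwise.
    """

    points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourError(f"expected an (N, 2) array, got shape {pts.shape}")
        if len(pts) < MIN_POINTS:
            raise ContourError(f"contour needs >= {MIN_POINTS} points, got {len(pts)}")
        if not np.all(np.isfinite(pts)):
            raise ContourError("contour contains non-finite coordinates")
        # drop an explicit closing vertex if present
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
            if len(pts) < MIN_POINTS:
                raise ContourError(
                    f"contour needs >= {MIN_POINTS} distinct points, got {len(pts)}"
                )
        seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        if np.any(seg == 0.0):
            k = int(np.argmin(seg))
            raise ContourError(f"duplicate consecutive points at index {k}")
        a = signed_area(pts)
        if a == 0.0:
            raise ContourError("zero-area contour")
        if a < 0.0:  # normalize clockwise input to anticlockwise
            pts = pts[::-1].copy()
        if not shapely.geometry.Polygon(pts).is_valid:
            raise ContourError("contour is self-intersecting (not a simple polygon)")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def translated(self, shift) -> "Contour":
        return Contour(self.points + np.asarray(shift, dtype=float))

    def rolled(self, start: int) -> "Contour":
        """Cyclically relabel vertices so that ``start`` becomes index 0."""
        return Contour(np.roll(self.points, -start, axis=0))
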