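"""Geometric primitives on closed contours.

Centroid, area, arclength, angular remeshing, discrete curvature and the
per-point surface frame (outward normal, tangent, rotation angle) used by
the shell model.

Conventions
-----------
* contours are anticlockwise in a y-up frame (see :class:`~nuctract.contour.Contour`);
* the outward normal is the tangent rotated by −π/2;
* curvature is positive where the outline is locally convex;
* arclength ``s1`` runs anticlockwise with its origin at the rearmost
  (minimum-x) vertex, matching the arclength-profile plotting convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contour import Contour, signed_area
from .errors import ContourError, NotStarShapedError

__all__ = [
    "area",
    "centroid",
    "perimeter",
    "remesh_by_angle",
    "frames",
    "FrameField",
    "rear_index",
]

_UNIT_TOL = 1e-9


def area(contour: Contour) -> float:
    """Polygon area (μm²) by the shoelace formula; positive by orientation."""
    return signed_area(contour.points)


def perimeter(contour: Contour) -> float:
    """Total boundary length (μm), including the closing edge."""
    pts = contour.points
    return float(np.sum(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)))


def centroid(contour: Contour) -> np.ndarray:
    """Area-weighted centroid of the polygon (μm).

    Uses the closed-polygon centroid formula with the wrap-around edge
    (vertex N connects to vertex 1); independent of the starting vertex.
    """
    pts = contour.points
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if a == 0.0:
        raise ContourError("centroid undefined for zero-area polygon")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def rear_index(contour: Contour) -> int:
    """Index of the rearmost vertex (minimum x; ties broken by minimum y)."""
    pts = contour.points
    candidates = np.flatnonzero(pts[:, 0] == pts[:, 0].min())
    return int(candidates[np.argmin(pts[candidates, 1])])


def _ray_crossings(pts: np.ndarray, origin: np.ndarray, direction: np.ndarray):
    """Distances s > 0 where the ray ``origin + s*direction`` crosses the polyline.

    Each edge is treated as the half-open segment [p_i, p_{i+1}) so a vertex
    lying exactly on the ray is counted once.
    """
    a = pts - origin
    b = np.roll(pts, -1, axis=0) - origin
    ca = a[:, 0] * direction[1] - a[:, 1] * direction[0]
    cb = b[:, 0] * direction[1] - b[:, 1] * direction[0]
    # sign change of the cross product = the edge straddles the ray's line;
    # half-open so a vertex exactly on the line is counted once
    hit = ((ca >= 0.0) & (cb < 0.0)) | ((ca < 0.0) & (cb >= 0.0))
    if not np.any(hit):
        return np.empty(0)
    t = ca[hit] / (ca[hit] - cb[hit])
    px = a[hit, 0] + t * (b[hit, 0] - a[hit, 0])
    py = a[hit, 1] + t * (b[hit, 1] - a[hit, 1])
    s = px * direction[0] + py * direction[1]
    return s[s > 0.0]


def remesh_by_angle(contour: Contour, n: int, origin=None) -> Contour:
    """Resample a star-shaped contour at ``n`` equally spaced polar angles.

    Point ``k`` is the unique intersection of the boundary with the ray from
    ``origin`` (default: polygon centroid) at angle ``θ_k = −π + 2πk/n``.
    Raises :class:`NotStarShapedError` (naming the offending angle) if any
    ray crosses the boundary zero or more than one time.
    """
    if n < 8:
        raise ContourError(f"remesh needs n >= 8 points, got {n}")
    o = centroid(contour) if origin is None else np.asarray(origin, dtype=float)
    pts = contour.points
    thetas = -np.pi + 2.0 * np.pi * np.arange(n) / n
    out = np.empty((n, 2))
    for k, th in enumerate(thetas):
        d = np.array([np.cos(th), np.sin(th)])
        s = _ray_crossings(pts, o, d)
        if len(s) != 1:
            raise NotStarShapedError(th, len(s))
        out[k] = o + s[0] * d
    return Contour(out)


@dataclass(frozen=True)
class FrameField:
    """Per-vertex surface frame of a contour.

    Arrays are aligned with the vertex order of the contour they were
    computed from.  ``s1`` is the anticlockwise arclength coordinate with its
    zero at the rearmost (minimum-x) vertex, wrapped into ``[0, perimeter)``;
    it is strictly increasing whenever the contour itself starts at the rear.
    """

    points: np.ndarray = field(repr=False)
    s1: np.ndarray = field(repr=False)
    normal: np.ndarray = field(repr=False)
    tangent: np.ndarray = field(repr=False)
    phi: np.ndarray = field(repr=False)
    curvature: np.ndarray = field(repr=False)
    total_length: float = 0.0

    def __post_init__(self) -> None:
        n_norm = np.linalg.norm(self.normal, axis=1)
        t_norm = np.linalg.norm(self.tangent, axis=1)
        if np.any(np.abs(n_norm - 1.0) > _UNIT_TOL) or np.any(np.abs(t_norm - 1.0) > _UNIT_TOL):
            raise ContourError("frame vectors are not unit length")
        dot = np.einsum("ij,ij->i", self.normal, self.tangent)
        if np.any(np.abs(dot) > _UNIT_TOL):
            raise ContourError("normal and tangent are not orthogonal")

    def __len__(self) -> int:
        return len(self.points)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s1_um": self.s1,
                "x_um": self.points[:, 0],
                "y_um": self.points[:, 1],
                "nx": self.normal[:, 0],
                "ny": self.normal[:, 1],
                "phi_rad": self.phi,
                "curvature_per_um": self.curvature,
            }
        )


def frames(contour: Contour) -> FrameField:
    """Discrete surface frame of a closed contour.

    Tangents are periodic central differences of the vertex positions,
    normalized; the outward normal is the tangent rotated by −π/2 (outward
    because contours are anticlockwise); ``phi = atan2(n_y, n_x)``.
    Curvature at vertex *i* is the turning angle between the two adjacent
    edge vectors divided by their mean length (positive where convex).
    """
    pts = contour.points
    edges = np.roll(pts, -1, axis=0) - pts          # e_i = p_{i+1} - p_i
    elen = np.linalg.norm(edges, axis=1)
    if np.any(elen == 0.0):
        raise ContourError("duplicate consecutive points")

    chord = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    tangent = chord / np.linalg.norm(chord, axis=1, keepdims=True)
    normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])
    phi = np.arctan2(normal[:, 1], normal[:, 0])

    prev_e = np.roll(edges, 1, axis=0)
    turn = np.arctan2(
        prev_e[:, 0] * edges[:, 1] - prev_e[:, 1] * edges[:, 0],
        np.einsum("ij,ij->i", prev_e, edges),
    )
    mean_len = 0.5 * (np.roll(elen, 1) + elen)
    curvature = turn / mean_len

    cum = np.concatenate([[0.0], np.cumsum(elen)])
    total = cum[-1]
    rear = rear_index(contour)
    s1 = np.mod(cum[:-1] - cum[rear], total)
    s1[rear] = 0.0

    return FrameField(
        points=pts,
        s1=s1,
        normal=normal,
        tangent=tangent,
        phi=phi,
        curvature=curvature,
        total_length=float(total),
    )
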