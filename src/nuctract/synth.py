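"""Synthetic contours, deformation pairs and images for testing and demos.

Everything is generated programmatically: star-shaped stage-like outlines
(circle, ellipse, stadium, channel shapes), deformation pairs with known
ground-truth per-point displacement, and rasterized grayscale images that
close the loop with the segmentation code.  No experimental data required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour import Contour
from .contour_io import DEFAULT_PIXEL_SIZE, GrayImage
from .errors import ContourError
from .geometry import area, centroid

__all__ = [
    "ChannelGeometry",
    "make_shape",
    "make_deformation_pair",
    "DeformationPair",
    "rasterize",
    "SHAPE_KINDS",
    "MAP_KINDS",
]

SHAPE_KINDS = ("circle", "ellipse", "stadium", "pre-constriction", "entering", "inside")
MAP_KINDS = ("translation", "dilation", "area-preserving-affine", "constriction-squeeze")


@dataclass(frozen=True)
class ChannelGeometry:
    """Microchannel/constriction dimensions (μm).

    Defaults: 7 × 4.7 channel, 2 × 3.4 constriction, 20 long, 45° taper.
    The constriction occupies ``constriction_start <= x <= constriction_start
    + constriction_length``.
    """

    channel_width: float = 7.0
    channel_height: float = 4.7
    constriction_width: float = 2.0
    constriction_height: float = 3.4
    constriction_length: float = 20.0
    taper_angle_deg: float = 45.0
    constriction_start: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.constriction_width < self.channel_width):
            raise ValueError("constriction width must be < channel width")
        if not (0 < self.constriction_height < self.channel_height):
            raise ValueError("constriction height must be < channel height")
        if self.constriction_length <= 0:
            raise ValueError("constriction length must be positive")

    def height_at(self, x: np.ndarray) -> np.ndarray:
        """Channel height as a function of x position."""
        x = np.asarray(x, dtype=float)
        inside = (x >= self.constriction_start) & (
            x <= self.constriction_start + self.constriction_length
        )
        return np.where(inside, self.constriction_height, self.channel_height)


def _polar_shape(radius_fn, n_points: int, center) -> Contour:
    th = -np.pi + 2.0 * np.pi * np.arange(n_points) / n_points
    r = radius_fn(th)
    if np.any(r <= 0):
        raise ContourError("radius function must be positive everywhere")
    pts = np.column_stack([r * np.cos(th), r * np.sin(th)]) + np.asarray(center, float)
    return Contour(pts)


def _stadium(r: float, flat_half: float, n_points: int, center) -> Contour:
    """Two semicircular caps of radius r joined by flats of length 2·flat_half."""
    arc = np.pi * r
    total = 2 * arc + 4 * flat_half
    s = np.linspace(0.0, total, n_points, endpoint=False)
    pts = np.empty((n_points, 2))
    for i, si in enumerate(s):
        if si < arc:  # right cap, from (flat_half, -r) anticlockwise
            a = -np.pi / 2 + si / r
            pts[i] = (flat_half + r * np.cos(a), r * np.sin(a))
        elif si < arc + 2 * flat_half:  # top flat, moving -x
            pts[i] = (flat_half - (si - arc), r)
        elif si < 2 * arc + 2 * flat_half:  # left cap
            a = np.pi / 2 + (si - arc - 2 * flat_half) / r
            pts[i] = (-flat_half + r * np.cos(a), r * np.sin(a))
        else:  # bottom flat, moving +x
            pts[i] = (-flat_half + (si - 2 * arc - 2 * flat_half), -r)
    return Contour(pts + np.asarray(center, float))


def make_shape(kind: str, n_points: int = 200, center=(0.0, 0.0),
               geometry: ChannelGeometry | None = None, **params) -> Contour:
    """Star-shaped synthetic outline emulating the migration-stage shapes.

    Kinds: ``circle`` (radius), ``ellipse`` (a, b), ``stadium`` (radius,
    flat_length), ``pre-constriction``, ``entering`` (tip_length), ``inside``
    (length).  Channel-aware kinds respect ``geometry``: flats at the wall
    positions, width within the constriction <= constriction width.
    """
    if n_points < 32:
        raise ContourError(f"need >= 32 points, got {n_points}")
    geom = geometry if geometry is not None else ChannelGeometry()
    half_channel = geom.channel_width / 2.0
    half_constr = geom.constriction_width / 2.0

    if kind == "circle":
        radius = float(params.get("radius", 5.0))
        if radius <= 0:
            raise ContourError("radius must be positive")
        return _polar_shape(lambda th: np.full_like(th, radius), n_points, center)

    if kind == "ellipse":
        a = float(params.get("a", 5.0))
        b = float(params.get("b", 3.0))
        if a <= 0 or b <= 0:
            raise ContourError("ellipse semi-axes must be positive")

        def r_ell(th):
            return a * b / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)

        return _polar_shape(r_ell, n_points, center)

    if kind == "stadium":
        r = float(params.get("radius", 2.0))
        flat = float(params.get("flat_length", 6.0))
        if r <= 0 or flat <= 0:
            raise ContourError("stadium dimensions must be positive")
        return _stadium(r, flat / 2.0, n_points, center)

    if kind == "pre-constriction":
        # rounded blob clipped flat at the channel walls
        a = float(params.get("a", 5.5))
        b = float(params.get("b", half_channel * 1.25))
        if a <= 0:
            raise ContourError("shape dimensions must be positive")

        def r_pre(th):
            r_ell = a * b / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)
            with np.errstate(divide="ignore"):
                r_wall = np.where(np.abs(np.sin(th)) > 1e-12,
                                  half_channel / np.abs(np.sin(th)), np.inf)
            return np.minimum(r_ell, r_wall)

        return _polar_shape(r_pre, n_points, center)

    if kind == "entering":
        # channel-filling blob with a narrow tip protruding forward (+x)
        tip = float(params.get("tip_length", 3.0))
        if tip < 0:
            raise ContourError("tip_length must be non-negative")
        a = float(params.get("a", 5.0))
        b = float(params.get("b", half_channel * 1.2))
        # tip bump narrow enough that its lateral extent fits the constriction
        theta_w = float(params.get("tip_width_rad", half_constr / (a + tip)))

        def r_ent(th):
            r_ell = a * b / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)
            bump = tip * np.exp(-0.5 * (th / theta_w) ** 2)
            with np.errstate(divide="ignore"):
                r_wall = np.where(np.abs(np.sin(th)) > 1e-12,
                                  half_channel / np.abs(np.sin(th)), np.inf)
            return np.minimum(r_ell + bump, r_wall)

        return _polar_shape(r_ent, n_points, center)

    if kind == "inside":
        # elongated capsule that fits the constriction laterally
        length = float(params.get("length", 12.0))
        r = half_constr * float(params.get("fill_fraction", 1.0))
        if length <= 2 * r:
            raise ContourError("inside shape must be longer than its width")
        return _stadium(r, (length - 2 * r) / 2.0, n_points, center)

    raise ContourError(f"unknown shape kind {kind!r}; choose from {SHAPE_KINDS}")


@dataclass(frozen=True)
class DeformationPair:
    """Initial/target outlines with the exact ground-truth displacement."""

    initial: Contour
    target: Contour
    u_true: np.ndarray

    @property
    def mapping(self):
        from .elasticity import PointMapping

        return PointMapping(self.initial, self.target)


def make_deformation_pair(contour: Contour, map_kind: str, magnitude: float = 0.1,
                          geometry: ChannelGeometry | None = None) -> DeformationPair:
    """Apply an exact analytic map to a contour; keep per-point ground truth.

    Kinds: ``translation`` (shift +x by magnitude), ``dilation`` (isotropic
    1+magnitude about the centroid), ``area-preserving-affine``
    (diag(λ, 1/λ), λ = 1+magnitude, about the centroid; area preserved to
    1e-9 relative), ``constriction-squeeze`` (smooth lateral squeeze of the
    forward part into the constriction mouth, x rescaled so the area changes
    by < 1%).
    """
    pts = contour.points
    c = centroid(contour)

    if map_kind == "translation":
        target_pts = pts + np.array([magnitude, 0.0])
    elif map_kind == "dilation":
        target_pts = c + (1.0 + magnitude) * (pts - c)
    elif map_kind == "area-preserving-affine":
        lam = 1.0 + magnitude
        rel = pts - c
        target_pts = c + np.column_stack([lam * rel[:, 0], rel[:, 1] / lam])
    elif map_kind == "constriction-squeeze":
        geom = geometry if geometry is not None else ChannelGeometry()
        target_pts = _squeeze_map(pts, c, geom, magnitude)
    else:
        raise ContourError(f"unknown map kind {map_kind!r}; choose from {MAP_KINDS}")

    target = Contour(target_pts)  # raises if the image is not simple
    return DeformationPair(contour, target, target_pts - pts)


def _squeeze_map(pts: np.ndarray, c: np.ndarray, geom: ChannelGeometry,
                 magnitude: float) -> np.ndarray:
    """Squeeze |y| toward the constriction half-width ahead of its mouth."""
    x0 = geom.constriction_start
    half_constr = geom.constriction_width / 2.0
    taper = max(np.tan(np.radians(geom.taper_angle_deg)), 1e-6)
    blend = (geom.channel_width - geom.constriction_width) / (2.0 * taper)

    x, y = pts[:, 0], pts[:, 1]
    # 0 behind the mouth, ramping smoothly to 1 inside
    t = np.clip((x - (x0 - blend)) / blend, 0.0, 1.0)
    w = t * t * (3.0 - 2.0 * t)
    ymax = np.abs(y).max()
    target_scale = half_constr / max(ymax, half_constr)
    scale = 1.0 - w * magnitude * (1.0 - target_scale)
    y_new = y * scale
    out = np.column_stack([x, y_new])
    # restore the area with a uniform x rescale about the centroid
    from .contour import signed_area

    a0 = signed_area(pts)
    a1 = signed_area(out)
    out[:, 0] = c[0] + (out[:, 0] - c[0]) * (a0 / a1)
    return out


def rasterize(contour: Contour, pixel_size: float = DEFAULT_PIXEL_SIZE,
              noise_sd: float = 0.0, margin_px: int = 5,
              foreground: float = 1.0, background: float = 0.0,
              seed: int = 0, shape: tuple[int, int] | None = None) -> GrayImage:
    """Fill a contour into a grayscale image (optionally noisy), y up.

    The frame is sized from the bounding box plus ``margin_px`` unless
    ``shape`` is given; a contour exceeding a given frame is an error.
    """
    from skimage.draw import polygon as sk_polygon

    pts = contour.points
    if margin_px < 2:
        raise ValueError("need >= 2 px margin")
    cols = pts[:, 0] / pixel_size
    if shape is None:
        min_c, max_c = cols.min(), cols.max()
        y_px = pts[:, 1] / pixel_size
        min_r, max_r = y_px.min(), y_px.max()
        if max_c - min_c < 1 or max_r - min_r < 1:
            raise ContourError("contour is smaller than one pixel")
        width = int(np.ceil(max_c - min_c)) + 2 * margin_px + 1
        height = int(np.ceil(max_r - min_r)) + 2 * margin_px + 1
        col_off = margin_px - min_c
        row_top = max_r + margin_px
    else:
        height, width = shape
        col_off = 0.0
        row_top = (height - 1) * 1.0
        y_px = pts[:, 1] / pixel_size
        if (cols.min() < margin_px or cols.max() > width - 1 - margin_px
                or y_px.min() < margin_px or y_px.max() > height - 1 - margin_px):
            raise ContourError("contour exceeds the requested frame")

    col = cols + col_off
    row = row_top - pts[:, 1] / pixel_size
    img = np.full((height, width), background, dtype=float)
    rr, cc = sk_polygon(row, col, shape=img.shape)
    img[rr, cc] = foreground
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return GrayImage(img, pixel_size)
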