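"""Image segmentation and contour file I/O.

Reads grayscale nucleus images (TIFF/PNG), thresholds them (Otsu), extracts
the outer boundary of the largest object and converts it to a physical-unit
:class:`~nuctract.contour.Contour`.  Also round-trips contours through a
two-column CSV format (header ``x_um,y_um``) and estimates volumes from
projected area times channel height.

Pixel convention: coordinates are 0-based pixel centres; the image row axis
is flipped on conversion so that y increases upward in the physical frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
from skimage import measure

from .contour import Contour, MIN_POINTS
from .errors import ContourParseError, DegenerateImageError, NoObjectError

DEFAULT_PIXEL_SIZE = 0.215  # μm / pixel

__all__ = [
    "GrayImage",
    "otsu_threshold",
    "otsu_from_histogram",
    "extract_contour",
    "read_contour_csv",
    "write_contour_csv",
    "read_image",
    "read_image_series",
    "estimate_volume",
    "DEFAULT_PIXEL_SIZE",
]


@dataclass(frozen=True)
class GrayImage:
    """Single-channel intensity image with a physical pixel size (μm/pixel)."""

    pixels: np.ndarray = field(repr=False)
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"image must be at least 2x2, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image intensities must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        px.setflags(write=False)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self):
        return self.pixels.shape


def otsu_from_histogram(counts: np.ndarray, centers: np.ndarray) -> float:
    """Threshold maximizing the between-class variance of a histogram.

    Candidate thresholds lie between consecutive bins; ties are broken to the
    lowest maximizing threshold so the result is deterministic.  Returns the
    midpoint between the last bin of the lower class and the first bin of the
    upper class.
    """
    counts = np.asarray(counts, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if np.count_nonzero(counts) < 2:
        raise DegenerateImageError("histogram has fewer than 2 occupied bins")

    # cumulative class weights and means; candidate t splits bins [0..t] | [t+1..]
    w0 = np.cumsum(counts)[:-1]
    w1 = w0[-1] + counts[-1] - w0
    m = np.cumsum(counts * centers)
    m0 = m[:-1]
    m1 = m[-1] - m0
    valid = (w0 > 0) & (w1 > 0)
    between = np.full(len(w0), -np.inf)
    between[valid] = (
        w0[valid] * w1[valid]
        * (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
    )
    split = int(np.argmax(between))  # argmax takes the first (lowest) maximizer
    return 0.5 * (centers[split] + centers[split + 1])


def otsu_threshold(image: GrayImage, nbins: int = 256) -> float:
    """Otsu intensity threshold of an image (between-class variance maximizer)."""
    px = image.pixels
    if px.min() == px.max():
        raise DegenerateImageError("constant image: no threshold separates classes")
    counts, edges = np.histogram(px.ravel(), bins=nbins, range=(px.min(), px.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return otsu_from_histogram(counts, centers)


def extract_contour(image: GrayImage, threshold: float, spacing_px: float = 1.0) -> Contour:
    """Trace the outline of the largest above-threshold object.

    Binarizes at ``threshold``, keeps the largest 8-connected component,
    fills holes, traces the outer sub-pixel boundary (marching squares at
    level 0.5 on the padded mask, which follows the outer pixel edges), then
    resamples the polyline to points spaced ``spacing_px`` pixels apart and
    converts to μm with y up.

    A component touching the image border triggers a warning but proceeds.
    """
    mask = image.pixels > threshold
    if not mask.any():
        raise NoObjectError("no pixels above threshold")
    labels, n_lab = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_lab + 1))
    biggest = 1 + int(np.argmax(sizes))
    comp = ndi.binary_fill_holes(labels == biggest)

    border = (
        comp[0, :].any() or comp[-1, :].any() or comp[:, 0].any() or comp[:, -1].any()
    )
    if border:
        warnings.warn("object touches the image border; outline may be clipped",
                      stacklevel=2)

    padded = np.pad(comp.astype(float), 1)
    rings = measure.find_contours(padded, 0.5, fully_connected="high")
    if not rings:
        raise NoObjectError("could not trace a boundary")
    ring = max(rings, key=len) - 1.0  # undo padding; (row, col) vertices

    # resample to uniform spacing along the boundary
    closed = np.vstack([ring, ring[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n_out = max(int(round(total / spacing_px)), MIN_POINTS)
    s_new = np.linspace(0.0, total, n_out, endpoint=False)
    rows = np.interp(s_new, cum, closed[:, 0])
    cols = np.interp(s_new, cum, closed[:, 1])

    h = image.pixels.shape[0]
    x = cols * image.pixel_size
    y = (h - 1 - rows) * image.pixel_size
    return Contour(np.column_stack([x, y]))


def read_image(path, pixel_size: float = DEFAULT_PIXEL_SIZE) -> GrayImage:
    """Read a single-channel TIFF or PNG image."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = arr[0] if arr.shape[0] < arr.shape[-1] else arr[..., 0]
    return GrayImage(arr, pixel_size)


def read_image_series(path, pixel_size: float = DEFAULT_PIXEL_SIZE) -> list[GrayImage]:
    """Read a multi-page TIFF as a list of frames (time series)."""
    import tifffile

    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return [GrayImage(frame, pixel_size) for frame in arr]


def write_contour_csv(contour: Contour, path) -> None:
    """Write a contour as ``x_um,y_um`` CSV, one vertex per line, implicit closure."""
    with open(path, "w") as fh:
        fh.write("x_um,y_um\n")
        for x, y in contour.points:
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def read_contour_csv(path) -> Contour:
    """Read a two-column contour CSV; orientation is normalized to anticlockwise."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ContourParseError(f"expected 2 columns, got {len(parts)}", ln)
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                if ln == 1:
                    continue  # header line
                raise ContourParseError(str(exc), ln) from exc
    if len(rows) < MIN_POINTS:
        raise ContourParseError(f"contour needs >= {MIN_POINTS} points, got {len(rows)}")
    return Contour(np.array(rows))


def estimate_volume(contour: Contour, height: float) -> float:
    """Projected polygon area times channel height (μm³).

    For outlines spanning a region where the channel height changes, split
    the polygon at the region boundaries and sum the per-region results
    (see :func:`nuctract.cli.volume_report` for the channel-aware version).
    """
    from .geometry import area

    if height <= 0:
        raise ValueError("height must be positive")
    return area(contour) * height
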