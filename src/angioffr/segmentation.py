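"""Semi-automatic vessel extraction from a single 2-D grayscale angiogram.

The workflow mirrors desk QCA: the user drops ordered seed points along the
vessel of interest; :func:`trace_centerline` refines a polyline through the
seeds onto the local intensity ridge, and :func:`measure_diameters` scans
perpendicular to the centerline, locating each lumen edge at the half-height
crossing between the local vessel-core and background intensity (sub-pixel
by linear interpolation).  The result is the standard arc-length / diameter
profile consumed by :mod:`angioffr.geometry`.

Coordinates are (row, col) pixel coordinates, 0-based, with pixel centers
at integer positions.  Only single-frame stills are handled; TIMI frame
counting remains numeric user input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DomainError, QualityFailureError, TraceFailureError
from .geometry import CenterlineProfile

__all__ = [
    "AngiogramImage",
    "VesselContours",
    "trace_centerline",
    "measure_diameters",
]

log = logging.getLogger(__name__)

_SCAN_STEP = 0.25  # px; sub-pixel sampling step along perpendicular scanlines
_MIN_CONTRAST = 0.2  # fraction of the global intensity range a vessel must show


@dataclass(frozen=True)
class AngiogramImage:
    """Grayscale angiographic still with physical pixel spacing.

    ``polarity`` is 'dark' when the contrast-filled vessel is darker than
    background (the usual cine convention) or 'bright' when inverted.
    """

    pixels: np.ndarray
    pixel_spacing: float  # mm per pixel, isotropic
    polarity: str = "dark"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2 or min(px.shape) < 64:
            raise DomainError("image must be 2-D grayscale of at least 64x64 pixels")
        if self.pixel_spacing <= 0:
            raise DomainError("pixel_spacing must be positive")
        if self.polarity not in ("dark", "bright"):
            raise DomainError("polarity must be 'dark' or 'bright'")

    def dark_vessel_view(self) -> np.ndarray:
        """Pixels with the vessel guaranteed darker than background."""
        return self.pixels if self.polarity == "dark" else -self.pixels


@dataclass(frozen=True)
class VesselContours:
    """Sub-pixel centerline with per-point left/right lumen edge crossings."""

    centerline: np.ndarray  # (N, 2) (row, col)
    left_edge: np.ndarray   # (N, 2)
    right_edge: np.ndarray  # (N, 2)

    def __post_init__(self) -> None:
        if not (len(self.centerline) == len(self.left_edge) == len(self.right_edge)):
            raise DomainError("contour arrays must have equal length")


def _scan(img: np.ndarray, point: np.ndarray, normal: np.ndarray, half_width: float):
    """Sample intensity along the perpendicular; returns (offsets px, values)."""
    offsets = np.arange(-half_width, half_width + 1e-9, _SCAN_STEP)
    coords = point[:, None] + normal[:, None] * offsets[None, :]
    vals = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
    return offsets, vals


def _lumen_crossings(offsets: np.ndarray, vals: np.ndarray, contrast_floor: float):
    """Half-height lumen edges around the darkest point of one scanline.

    Returns (left_offset, right_offset, center_offset) in px, or None when
    the scan shows no convincing vessel (insufficient contrast or no
    crossing inside the window).
    """
    k = int(np.argmin(vals))
    core = vals[k]
    edge_n = max(3, len(vals) // 8)
    bg = max(np.median(vals[:edge_n]), np.median(vals[-edge_n:]))
    if bg - core < contrast_floor:
        return None
    half = 0.5 * (core + bg)
    left = right = None
    for i in range(k, 0, -1):  # walk outward to the left half-height crossing
        if vals[i - 1] >= half > vals[i]:
            t = (half - vals[i]) / (vals[i - 1] - vals[i])
            left = offsets[i] - t * _SCAN_STEP
            break
    for i in range(k, len(vals) - 1):
        if vals[i + 1] >= half > vals[i]:
            t = (half - vals[i]) / (vals[i + 1] - vals[i])
            right = offsets[i] + t * _SCAN_STEP
            break
    if left is None or right is None:
        return None
    return left, right, 0.5 * (left + right)


def _polyline_normals(points: np.ndarray) -> np.ndarray:
    tangents = np.gradient(points, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangents /= norms
    return np.column_stack([-tangents[:, 1], tangents[:, 0]])


def _arclength_resample(points: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    n = max(2, int(round(total / spacing)) + 1)
    ti = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(ti, t, points[:, 0]), np.interp(ti, t, points[:, 1])])


def trace_centerline(
    image: AngiogramImage,
    seed_points: np.ndarray,
    search_half_width: float = 10.0,
    spacing: float = 1.0,
    n_refine: int = 3,
    seeds_proximal_to_distal: bool = True,
) -> np.ndarray:
    """Refine a user-seeded polyline onto the vessel's intensity ridge.

    The seeds (>= 2 ordered (row, col) points on or near the vessel) are
    densified to ~``spacing`` px and each point is pulled to the lumen
    center of its perpendicular scanline (midpoint of the two half-height
    edges) over ``n_refine`` passes.  The result is arc-length
    parameterized; when ``seeds_proximal_to_distal`` is False the output is
    reversed so it always runs proximal to distal.
    """
    seeds = np.asarray(seed_points, dtype=float)
    if seeds.ndim != 2 or seeds.shape[0] < 2 or seeds.shape[1] != 2:
        raise DomainError("need >= 2 ordered (row, col) seed points")
    img = image.dark_vessel_view()
    h, w = img.shape
    for i, (r, c) in enumerate(seeds):
        if not (0 <= r < h and 0 <= c < w):
            raise TraceFailureError(f"seed {i} at ({r:.0f}, {c:.0f}) outside image", i)
    contrast_floor = _MIN_CONTRAST * max(float(img.max() - img.min()), 1e-12)

    # validate every seed individually: some scan direction through it must
    # show a vessel, regardless of how the polyline happens to be oriented
    probe_dirs = [np.array([np.cos(a), np.sin(a)]) for a in np.arange(0, np.pi, np.pi / 4)]
    for i, seed in enumerate(seeds):
        for direction in probe_dirs:
            offs, vals = _scan(img, seed, direction, search_half_width)
            if _lumen_crossings(offs, vals, contrast_floor) is not None:
                break
        else:
            raise TraceFailureError(
                f"seed {i} not on a vessel within the search half-width", i
            )

    points = _arclength_resample(seeds, spacing)
    for _ in range(n_refine):
        normals = _polyline_normals(points)
        for j in range(len(points)):
            offs, vals = _scan(img, points[j], normals[j], search_half_width)
            hit = _lumen_crossings(offs, vals, contrast_floor)
            if hit is not None:
                points[j] = points[j] + normals[j] * hit[2]
        # light smoothing keeps the polyline from zig-zagging on noise
        if len(points) > 4:
            points[1:-1] = (points[:-2] + 2 * points[1:-1] + points[2:]) / 4.0
        points = _arclength_resample(points, spacing)
    if not seeds_proximal_to_distal:
        points = points[::-1].copy()
    return points


def measure_diameters(
    image: AngiogramImage,
    centerline: np.ndarray,
    scan_half_width: float = 15.0,
    max_dropped_frac: float = 0.20,
) -> tuple[CenterlineProfile, VesselContours]:
    """Per-point lumen diameters via half-height edge detection.

    At each centerline sample the perpendicular scanline is sampled at
    quarter-pixel resolution; the two lumen edges sit at the half-height
    crossings between local core and background intensity, and the diameter
    is their separation times the pixel spacing.  Samples with no
    detectable edge pair are dropped (logged); if more than
    ``max_dropped_frac`` of samples drop, the image fails quality review.
    """
    pts = np.asarray(centerline, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise DomainError("centerline must be an (N>=2, 2) array")
    img = image.dark_vessel_view()
    contrast_floor = _MIN_CONTRAST * max(float(img.max() - img.min()), 1e-12)
    normals = _polyline_normals(pts)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc_px = np.concatenate([[0.0], np.cumsum(seg)])

    s_mm, d_mm, keep_pts, lefts, rights = [], [], [], [], []
    dropped = 0
    for j in range(len(pts)):
        offs, vals = _scan(img, pts[j], normals[j], scan_half_width)
        hit = _lumen_crossings(offs, vals, contrast_floor)
        if hit is None:
            dropped += 1
            continue
        left, right, _ = hit
        s_mm.append(arc_px[j] * image.pixel_spacing)
        d_mm.append((right - left) * image.pixel_spacing)
        keep_pts.append(pts[j])
        lefts.append(pts[j] + normals[j] * left)
        rights.append(pts[j] + normals[j] * right)
    if dropped:
        log.info("dropped %d/%d diameter samples with no edge pair", dropped, len(pts))
    if dropped > max_dropped_frac * len(pts) or len(s_mm) < 2:
        raise QualityFailureError(
            f"{dropped}/{len(pts)} samples unmeasurable; image fails quality review"
        )
    profile = CenterlineProfile(
        s=np.asarray(s_mm), d=np.asarray(d_mm), pixel_spacing=image.pixel_spacing
    )
    contours = VesselContours(
        centerline=np.asarray(keep_pts),
        left_edge=np.asarray(lefts),
        right_edge=np.asarray(rights),
    )
    return profile, contours
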