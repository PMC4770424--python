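"""Extract a polar outline of the responsive area from one response map.

The chain follows the outlining procedure used for widefield tonal
responses: trim a window around the target region, binarize at >60% of the
window peak, keep only the largest responsive island, increase the pixel
density 50×50-fold by block replication, detect the contour with a Sobel
filter (RMS of the horizontal and vertical kernel responses), take the
centroid of the contour pixels, and record the center-to-contour distance
in angular bins of 0.05° (7200 samples per outline).

Angle convention: 0° points along +x = +RC (caudal), angles increase
counterclockwise toward +DV (dorsal); image rows run ventral-to-dorsal
top-down, so θ = atan2(−Δrow, Δcol).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure

from .response import ResponseMap

__all__ = [
    "RegionMask",
    "PolarOutline",
    "trim",
    "binarize",
    "largest_island",
    "upsample",
    "sobel_edge",
    "outline_center",
    "polar_profile",
    "extract_outline",
    "SOBEL_H",
    "SOBEL_V",
]

#: Horizontal-direction Sobel kernel; the vertical kernel is its transpose.
SOBEL_H = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)
SOBEL_V = SOBEL_H.T.copy()


@dataclass
class RegionMask:
    """Binary mask of one responsive area.

    ``origin`` is the (row, col) of the mask's upper-left pixel in the
    parent response map, in *original* (pre-upsampling) pixels;
    ``upsample_factor`` is 1 for native-resolution masks.
    """

    values: np.ndarray
    pixel_pitch_um: float
    origin: tuple[int, int] = (0, 0)
    upsample_factor: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mask values must be binary (0/1)")
        self.values = self.values.astype(np.uint8)


@dataclass
class PolarOutline:
    """A closed contour as center + distance-vs-angle profile.

    ``angles_deg`` are bin left edges in [0, 360), strictly increasing;
    ``distances`` are the per-angle center-to-contour distances in
    ``unit`` ("px_up" for upsampled pixels, "um", or "mm"). Averaged
    outlines carry a per-angle SEM in ``dispersion`` and ``n_subjects``.
    ``center`` is in the parent map's coordinate frame ((row, col) original
    pixels for extracted outlines, (rc_mm, dv_mm) once placed), or None for
    center-free averaged shapes.
    """

    angles_deg: np.ndarray
    distances: np.ndarray
    unit: str
    center: tuple[float, float] | None = None
    dispersion: np.ndarray | None = None
    n_subjects: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.angles_deg.shape != self.distances.shape:
            raise ValueError("angles and distances must have the same length")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")
        if not np.all(self.distances > 0):
            raise ValueError("distances must be strictly positive")
        if self.dispersion is not None:
            self.dispersion = np.asarray(self.dispersion, dtype=float)
            if self.dispersion.shape != self.distances.shape:
                raise ValueError("dispersion must match the profile length")

    def to_mm(self, pixel_pitch_um: float | None = None) -> "PolarOutline":
        """Convert distances (and dispersion) to millimetres."""
        if self.unit == "mm":
            return self
        if self.unit == "um":
            scale = 1e-3
        elif self.unit == "px_up":
            if pixel_pitch_um is None:
                raise ValueError("pixel_pitch_um required to convert from pixels")
            scale = pixel_pitch_um * 1e-3
        else:
            raise ValueError(f"unknown unit {self.unit!r}")
        return PolarOutline(
            self.angles_deg,
            self.distances * scale,
            "mm",
            self.center,
            None if self.dispersion is None else self.dispersion * scale,
            self.n_subjects,
            dict(self.meta),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "unit": self.unit,
            "angle_convention": "0 deg = +RC (caudal), CCW toward +DV (dorsal)",
            "center": None if self.center is None else list(self.center),
            "n_subjects": self.n_subjects,
            "angles_deg": self.angles_deg.tolist(),
            "distances": self.distances.tolist(),
            "dispersion": None if self.dispersion is None else self.dispersion.tolist(),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PolarOutline":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["angles_deg"]),
            np.array(d["distances"]),
            d["unit"],
            None if d["center"] is None else tuple(d["center"]),
            None if d["dispersion"] is None else np.array(d["dispersion"]),
            d["n_subjects"],
            d.get("meta", {}),
        )


def trim(rmap: ResponseMap, bbox: tuple[int, int, int, int]) -> ResponseMap:
    """Crop ``rmap`` to ``bbox`` = (row_start, row_stop, col_start, col_stop).

    The crop origin is recorded so outline coordinates can be mapped back
    into the parent image.
    """
    r0, r1, c0, c1 = bbox
    h, w = rmap.values.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"bbox {bbox} empty or outside image of shape {(h, w)}")
    out = rmap.with_values(rmap.values[r0:r1, c0:c1])
    out.origin = (rmap.origin[0] + r0, rmap.origin[1] + c0)
    return out


def binarize(rmap: ResponseMap, frac: float = 0.6) -> RegionMask:
    """Threshold at > ``frac`` × the peak of the (trimmed) map.

    The inequality is strict: a pixel exactly at 60% of the peak is
    background.
    """
    peak = float(rmap.values.max())
    if peak <= 0:
        raise ValueError("map peak must be positive to binarize")
    mask = (rmap.values > frac * peak).astype(np.uint8)
    return RegionMask(mask, rmap.pixel_pitch_um, rmap.origin)


def largest_island(mask: RegionMask, connectivity: int = 2) -> RegionMask:
    """Keep only the largest connected foreground component.

    ``connectivity=2`` (8-connectivity) by default: pixels "abut" also
    diagonally. Ties go to the component whose first pixel comes earliest
    in (row, col) scan order — with scan-order labelling that is the
    lowest label, which ``argmax`` selects.
    """
    if mask.values.sum() == 0:
        raise ValueError("mask has no foreground pixels")
    labels = measure.label(mask.values, connectivity=connectivity)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = int(np.argmax(counts))
    return RegionMask(
        (labels == keep).astype(np.uint8),
        mask.pixel_pitch_um,
        mask.origin,
        mask.upsample_factor,
    )


def upsample(mask: RegionMask, fy: int = 50, fx: int = 50) -> RegionMask:
    """Increase pixel density by nearest-neighbour block replication.

    Each pixel becomes an ``fy``×``fx`` block (default 50×50 = 2500×
    density); the pixel pitch is divided accordingly. Isotropic factors
    are required so that distances stay meaningful.
    """
    if fy != fx:
        raise ValueError("anisotropic upsampling is not supported (fy must equal fx)")
    if fy < 1:
        raise ValueError("upsampling factor must be >= 1")
    up = np.kron(mask.values, np.ones((fy, fx), dtype=np.uint8))
    return RegionMask(
        up,
        mask.pixel_pitch_um / fy,
        mask.origin,
        mask.upsample_factor * fy,
    )


def sobel_edge(mask: RegionMask) -> np.ndarray:
    """Contour pixels of a binary mask via the 3×3 Sobel kernels.

    The horizontal kernel [[1,2,1],[0,0,0],[-1,-2,-1]] and its transpose
    are each convolved with the mask (reflective boundary), the two
    responses are combined as their root mean square, and every pixel with
    a nonzero combined magnitude is an edge pixel. Returns an (n, 2) array
    of (row, col) coordinates in the mask's (upsampled) pixel grid.
    """
    if min(mask.values.shape) < 3:
        raise ValueError("image must be at least 3x3 for the Sobel kernels")
    m = mask.values.astype(float)
    gh = ndimage.convolve(m, SOBEL_H, mode="reflect")
    gv = ndimage.convolve(m, SOBEL_V, mode="reflect")
    g = np.sqrt(gh**2 + gv**2)
    return np.argwhere(g > 0)


def outline_center(edge_px: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean (row, col) of the contour pixels."""
    edge_px = np.asarray(edge_px, dtype=float)
    if edge_px.size == 0:
        raise ValueError("empty edge set")
    r, c = edge_px.mean(axis=0)
    return float(r), float(c)


def _center_in_hull(edge_px: np.ndarray, center: tuple[float, float]) -> bool:
    hull = ConvexHull(edge_px.astype(float))
    eq = hull.equations  # A x + b <= 0 inside
    p = np.array(center, dtype=float)
    return bool(np.all(eq[:, :2] @ p + eq[:, 2] <= 1e-9))


def polar_profile(
    edge_px: np.ndarray,
    center: tuple[float, float],
    d_theta_deg: float = 0.05,
) -> PolarOutline:
    """Bin contour pixels into angular bins and average their distances.

    Every edge pixel is assigned the angle θ = atan2(−(row−c_row),
    col−c_col) (0° = +RC, CCW toward dorsal) and its Euclidean distance to
    the center; pixels are pooled into bins of ``d_theta_deg`` (7200 bins
    at the default 0.05°) and each bin's distance is the mean over its
    member pixels. Empty bins are filled by circular linear interpolation
    between the nearest occupied bins. Distances are in the mask's pixel
    units ("px_up").
    """
    edge_px = np.asarray(edge_px, dtype=float)
    if edge_px.size == 0:
        raise ValueError("empty edge set")
    if not _center_in_hull(edge_px, center):
        raise ValueError("center lies outside the convex hull of the edge pixels")
    n_bins = int(round(360.0 / d_theta_deg))
    dr = edge_px[:, 0] - center[0]
    dc = edge_px[:, 1] - center[1]
    theta = np.degrees(np.arctan2(-dr, dc)) % 360.0
    dist = np.hypot(dr, dc)
    idx = np.minimum((theta / d_theta_deg).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=dist, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    angles = np.arange(n_bins) * d_theta_deg
    occupied = counts > 0
    profile = np.empty(n_bins)
    profile[occupied] = sums[occupied] / counts[occupied]
    if not occupied.all():
        profile[~occupied] = np.interp(
            angles[~occupied], angles[occupied], profile[occupied], period=360.0
        )
    return PolarOutline(
        angles,
        profile,
        "px_up",
        center=center,
        meta={"d_theta_deg": d_theta_deg, "n_edge_pixels": int(len(edge_px))},
    )


def extract_outline(
    rmap: ResponseMap,
    bbox: tuple[int, int, int, int] | None = None,
    frac: float = 0.6,
    upsample_factor: int = 50,
    d_theta_deg: float = 0.05,
    connectivity: int = 2,
) -> PolarOutline:
    """Full outlining chain on one response map.

    trim → binarize (> ``frac``·peak) → largest island → ``upsample_factor``²
    density increase → Sobel contour → centroid → 0.05° polar profile.
    The returned outline has distances in μm and its center in the *parent*
    map's original-pixel frame (fractional row, col).
    """
    work = trim(rmap, bbox) if bbox is not None else rmap
    mask = largest_island(binarize(work, frac=frac), connectivity=connectivity)
    mask = upsample(mask, upsample_factor, upsample_factor)
    edges = sobel_edge(mask)
    center_up = outline_center(edges)
    prof = polar_profile(edges, center_up, d_theta_deg)
    # Upsampled pixel iu covers [iu/f - 0.5, (iu+1)/f - 0.5) of the original
    # pixel axis, so its center maps back to (iu + 0.5)/f - 0.5.
    f = upsample_factor
    center_orig = (
        work.origin[0] + (center_up[0] + 0.5) / f - 0.5,
        work.origin[1] + (center_up[1] + 0.5) / f - 0.5,
    )
    return PolarOutline(
        prof.angles_deg,
        prof.distances * mask.pixel_pitch_um,
        "um",
        center=center_orig,
        meta=dict(prof.meta, frac=frac, upsample_factor=f),
    )
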