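"""Assemble whole-region outlines at stereotaxic coordinates.

Per-animal polar outlines are averaged by angle across subjects,
downsampled from 0.05° to 5° sampling, and placed at the mean injection
site of their frequency band. For the four tonotopic regions (AAF, AI,
AII, DM) the low- and high-frequency outlines are bridged by four
intermediate outlines whose centers are equidistant along the straight
segment between the two sites and whose shapes morph linearly from one
outline to the other; the six small outlines are merged into the whole
regional outline. DA and DP (frequency-unorganized) keep their single
FM-response outline.

Axis convention: x = rc_mm from bregma (increasing caudally),
y = dv_mm from the dorsal edge of the rhinal fissure (increasing
dorsally).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

from .outline import PolarOutline

__all__ = [
    "InjectionSite",
    "SurfaceMap",
    "average_profiles",
    "downsample_profile",
    "intermediate_centers",
    "morph_outline",
    "place_outline",
    "merge_region",
    "build_surface_map",
    "read_sites_csv",
    "write_sites_csv",
]


@dataclass
class InjectionSite:
    """Stereotaxic center of one region/band response area.

    rc_mm: rostrocaudal distance from bregma (posterior positive);
    dv_mm: dorsoventral distance from the dorsal edge of the rhinal
    fissure (dorsal positive); n: number of subjects behind the mean.
    """

    region: str
    band: str
    rc_mm: float
    dv_mm: float
    n: int = 1
    sem_rc: float = 0.0
    sem_dv: float = 0.0
    #: Single noisy measurements may stray outside the atlas RC window;
    #: band means (the map inputs) must satisfy it, so it is on by default.
    check_range: bool = True

    def __post_init__(self) -> None:
        if self.check_range and not (2.0 <= self.rc_mm <= 4.0):
            raise ValueError(f"rc_mm {self.rc_mm} outside the atlas range [2.0, 4.0]")
        if self.check_range and self.dv_mm < 0:
            raise ValueError("dv_mm must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def center(self) -> tuple[float, float]:
        return (self.rc_mm, self.dv_mm)


@dataclass
class SurfaceMap:
    """The reconstructed cortical surface map.

    ``regions`` maps region label → merged polygon in (rc_mm, dv_mm);
    ``constituents`` retains each region's ordered small outlines
    (2 measured + 4 interpolated for tonotopic regions, 1 for DA/DP).
    """

    regions: dict[str, Polygon]
    constituents: dict[str, list[Polygon]]
    meta: dict = field(default_factory=dict)

    def to_geojson(self, path: str | Path | None = None) -> dict:
        def ring(poly: Polygon) -> list:
            return [list(map(float, xy)) for xy in poly.exterior.coords]

        payload = {
            "type": "FeatureCollection",
            "metadata": {
                "units": "mm",
                "x": "rc_mm from bregma (caudal positive)",
                "y": "dv_mm from rhinal fissure (dorsal positive)",
                **self.meta,
            },
            "features": [
                {
                    "type": "Feature",
                    "properties": {
                        "region": label,
                        "n_constituents": len(self.constituents[label]),
                    },
                    "geometry": {"type": "Polygon", "coordinates": [ring(poly)]},
                }
                for label, poly in self.regions.items()
            ],
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=1))
        return payload

    def to_svg(self, path: str | Path) -> None:
        """Simple SVG overlay of the merged regions and constituents."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for label, poly in self.regions.items():
            x, y = poly.exterior.xy
            ax.fill(x, y, alpha=0.3, label=label)
            for c in self.constituents[label]:
                cx, cy = c.exterior.xy
                ax.plot(cx, cy, lw=0.5, color="gray")
        ax.set_xlabel("RC from bregma (mm, caudal →)")
        ax.set_ylabel("DV from rhinal fissure (mm, dorsal →)")
        ax.set_aspect("equal")
        ax.legend(fontsize=7)
        fig.savefig(path, format="svg")
        plt.close(fig)


def average_profiles(profiles: Sequence[PolarOutline]) -> PolarOutline:
    """Per-angle mean and SEM of aligned polar profiles across subjects.

    Profiles are center-relative shapes; centers are deliberately *not*
    averaged here — stereotaxic centers come from the injection-site
    measurements, mirroring the separation of shape (imaging) from
    position (histology).
    """
    if len(profiles) == 0:
        raise ValueError("cannot average an empty list of profiles")
    first = profiles[0]
    for p in profiles[1:]:
        if p.distances.shape != first.distances.shape or not np.allclose(
            p.angles_deg, first.angles_deg
        ):
            raise ValueError("profiles must share the same angular bins")
        if p.unit != first.unit:
            raise ValueError("profiles must share the same unit")
    stack = np.stack([p.distances for p in profiles])
    mean = stack.mean(axis=0)
    n = len(profiles)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return PolarOutline(
        first.angles_deg.copy(),
        mean,
        first.unit,
        center=None,
        dispersion=sem,
        n_subjects=n,
    )


def downsample_profile(profile: PolarOutline, factor: int = 100) -> PolarOutline:
    """Average every ``factor`` consecutive samples (0.05° → 5° bins).

    Output sample k is the mean of the input samples in [5k°, 5(k+1)°);
    the per-angle SEM, when present, is block-averaged the same way as an
    indicative dispersion.
    """
    n = profile.distances.size
    if n % factor != 0:
        raise ValueError(f"profile length {n} is not divisible by {factor}")
    if n != 7200:
        raise ValueError("downsampling expects the full 7200-sample profile")
    k = n // factor
    d = profile.distances.reshape(k, factor).mean(axis=1)
    angles = profile.angles_deg[::factor].copy()
    disp = (
        None
        if profile.dispersion is None
        else profile.dispersion.reshape(k, factor).mean(axis=1)
    )
    return PolarOutline(
        angles, d, profile.unit, profile.center, disp, profile.n_subjects, dict(profile.meta)
    )


def intermediate_centers(
    low: InjectionSite | tuple[float, float],
    high: InjectionSite | tuple[float, float],
    k: int = 4,
) -> list[tuple[float, float]]:
    """``k`` points equidistantly spaced on the straight segment from the
    low- to the high-frequency site (fractions i/(k+1), i = 1..k)."""
    p0 = np.asarray(low.center if isinstance(low, InjectionSite) else low, dtype=float)
    p1 = np.asarray(high.center if isinstance(high, InjectionSite) else high, dtype=float)
    if np.allclose(p0, p1):
        raise ValueError("low and high sites coincide; no gradient to interpolate")
    return [tuple(p0 + (i / (k + 1)) * (p1 - p0)) for i in range(1, k + 1)]


def morph_outline(low: PolarOutline, high: PolarOutline, w: float) -> PolarOutline:
    """Shape-morph between two aligned profiles: d_w(θ) = (1−w)·d_low(θ) + w·d_high(θ)."""
    if low.distances.shape != high.distances.shape or not np.allclose(
        low.angles_deg, high.angles_deg
    ):
        raise ValueError("profiles must share the same angular samples")
    if not (0.0 <= w <= 1.0):
        raise ValueError("w must lie in [0, 1]")
    if low.unit != high.unit:
        raise ValueError("profiles must share the same unit")
    if w == 0.0:
        d = low.distances.copy()
    elif w == 1.0:
        d = high.distances.copy()
    else:
        d = (1.0 - w) * low.distances + w * high.distances
    return PolarOutline(low.angles_deg.copy(), d, low.unit, center=None, meta={"morph_w": w})


def place_outline(profile: PolarOutline, center: tuple[float, float]) -> Polygon:
    """Convert a polar profile in mm to a polygon anchored at ``center``.

    Vertex k sits at center + d(θ_k)·(cos θ_k, sin θ_k) in the
    (rc_mm, dv_mm) frame.
    """
    if profile.unit != "mm":
        raise ValueError(
            f"profile must be in mm before placement (got {profile.unit!r}); "
            "use PolarOutline.to_mm"
        )
    th = np.radians(profile.angles_deg)
    x = center[0] + profile.distances * np.cos(th)
    y = center[1] + profile.distances * np.sin(th)
    return Polygon(np.column_stack([x, y]))


def _resample_ring(poly: Polygon, step_deg: float = 2.5) -> Polygon:
    """Angular resampling of a polygon's exterior about its centroid.

    Rays at ``step_deg`` intervals are cast from the centroid and the
    outermost boundary intersection is kept, reducing the vertex count to
    360/step_deg points while smoothing the merged outline.
    """
    c = poly.centroid
    minx, miny, maxx, maxy = poly.bounds
    reach = 2.0 * max(maxx - minx, maxy - miny) + 1e-9
    boundary = poly.exterior
    pts = []
    for th in np.radians(np.arange(0.0, 360.0, step_deg)):
        ray = LineString(
            [(c.x, c.y), (c.x + reach * np.cos(th), c.y + reach * np.sin(th))]
        )
        hit = ray.intersection(boundary)
        if hit.is_empty:
            continue
        candidates = (
            [hit] if isinstance(hit, Point) else [g for g in getattr(hit, "geoms", [hit])]
        )
        best = None
        for g in candidates:
            for xy in getattr(g, "coords", []):
                d = np.hypot(xy[0] - c.x, xy[1] - c.y)
                if best is None or d > best[0]:
                    best = (d, xy)
        if best is not None:
            pts.append(best[1])
    return Polygon(pts) if len(pts) >= 3 else poly


def merge_region(outlines: Sequence[Polygon], resample_deg: float = 2.5) -> Polygon:
    """Geometric union of a region's constituent outlines.

    Consecutive constituents must pairwise overlap (four intermediates at
    the default spacing guarantee this when the inter-site gap is smaller
    than the outline diameters); a disjoint pair raises with the gap
    named, so the caller can raise the number of intermediates. The
    exterior ring of the union is angularly resampled at ``resample_deg``
    about the region centroid (≤ 144 vertices).
    """
    if len(outlines) == 0:
        raise ValueError("no outlines to merge")
    for i in range(len(outlines) - 1):
        if not outlines[i].intersects(outlines[i + 1]):
            raise ValueError(
                f"consecutive outlines {i} and {i + 1} are disjoint; "
                "increase the number of intermediate outlines"
            )
    union = unary_union(list(outlines))
    if union.geom_type != "Polygon":
        raise ValueError(f"union is not a single polygon ({union.geom_type})")
    merged = Polygon(union.exterior)
    if resample_deg and resample_deg > 0:
        merged = _resample_ring(merged, resample_deg)
    return merged


def build_surface_map(
    sites: Sequence[InjectionSite],
    averaged_outlines: Mapping[tuple[str, str], PolarOutline],
    k_intermediates: int = 4,
    resample_deg: float = 2.5,
) -> SurfaceMap:
    """Place, morph and merge the ten averaged outlines into six regions.

    ``sites`` supplies one mean injection site per (region, band);
    ``averaged_outlines`` one 72-sample profile in mm per (region, band).
    Tonotopic regions get 2 placed measured outlines + ``k_intermediates``
    morphed outlines at equidistant centers, merged; DA/DP their single
    placed outline.
    """
    from .synthetic import TONOTOPIC_REGIONS, REGIONS  # local import: no cycle at load

    site_map = {(s.region, s.band): s for s in sites}
    regions: dict[str, Polygon] = {}
    constituents: dict[str, list[Polygon]] = {}
    for region in REGIONS:
        if region in TONOTOPIC_REGIONS:
            keys = [(region, "low"), (region, "high")]
        else:
            keys = [(region, "fm")]
        for key in keys:
            if key not in site_map:
                raise ValueError(f"missing injection site for {key}")
            if key not in averaged_outlines:
                raise ValueError(f"missing averaged outline for {key}")
        if region in TONOTOPIC_REGIONS:
            lo_site, hi_site = site_map[keys[0]], site_map[keys[1]]
            lo_prof = averaged_outlines[keys[0]].to_mm()
            hi_prof = averaged_outlines[keys[1]].to_mm()
            centers = intermediate_centers(lo_site, hi_site, k_intermediates)
            polys = [place_outline(lo_prof, lo_site.center)]
            for i, c in enumerate(centers, start=1):
                w = i / (k_intermediates + 1)
                polys.append(place_outline(morph_outline(lo_prof, hi_prof, w), c))
            polys.append(place_outline(hi_prof, hi_site.center))
            regions[region] = merge_region(polys, resample_deg)
        else:
            prof = averaged_outlines[keys[0]].to_mm()
            polys = [place_outline(prof, site_map[keys[0]].center)]
            regions[region] = polys[0]
        constituents[region] = polys
    return SurfaceMap(
        regions,
        constituents,
        meta={"k_intermediates": k_intermediates, "resample_deg": resample_deg},
    )


SITE_COLUMNS = ["region", "band", "rc_mm", "dv_mm", "sem_rc", "sem_dv", "n"]


def read_sites_csv(path: str | Path) -> list[InjectionSite]:
    """Read an injection-site table (columns region, band, rc_mm, dv_mm,
    sem_rc, sem_dv, n)."""
    df = pd.read_csv(path)
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns {sorted(missing)}")
    return [
        InjectionSite(
            row.region,
            row.band,
            float(row.rc_mm),
            float(row.dv_mm),
            int(row.n),
            float(row.sem_rc),
            float(row.sem_dv),
        )
        for row in df.itertuples()
    ]


def write_sites_csv(sites: Sequence[InjectionSite], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "region": s.region,
                "band": s.band,
                "rc_mm": s.rc_mm,
                "dv_mm": s.dv_mm,
                "sem_rc": s.sem_rc,
                "sem_dv": s.sem_dv,
                "n": s.n,
            }
        for s in sites
        ]
    ).to_csv(path, index=False)
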