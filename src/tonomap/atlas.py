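"""Project the surface map onto coronal gridlines and measure slice coordinates.

Two jobs live here: (1) the stereotaxic boundary table — for each vertical
gridline (rostrocaudal positions 2.0–4.0 mm posterior to bregma at 0.2-mm
intervals) the ventral and dorsal dorsoventral extents of every region the
line crosses; (2) the rotated dorsoventral measurement used to read an
injection site's DV coordinate off a coronal slice image (the slice is
rotated clockwise by 15° so the view matches the imaging orientation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .reconstruct import SurfaceMap

__all__ = [
    "SlicePoint",
    "BoundaryTable",
    "measure_dv",
    "gridline_boundaries",
    "render_coronal_overlays",
]


@dataclass
class SlicePoint:
    """A point on a coronal slice image, with the dorsal tip of the rhinal
    fissure as reference. Coordinates in μm, x lateral (rightward), y
    dorsal (upward)."""

    x_um: float
    y_um: float
    reference: tuple[float, float] | None = None


def measure_dv(site: SlicePoint, rotation_deg: float = 15.0) -> float:
    """Dorsoventral coordinate of a slice point, in mm, after rotation.

    Both the site and its rhinal-fissure reference are rotated clockwise
    (as seen on the displayed slice; counterclockwise in the y-up frame)
    by ``rotation_deg`` about a common origin, and the DV value is the
    signed difference of the rotated y coordinates. Relative DV is
    invariant to the choice of rotation center.
    """
    if site.reference is None:
        raise ValueError("reference (dorsal tip of the rhinal fissure) not set")
    a = np.radians(rotation_deg)
    dx = site.x_um - site.reference[0]
    dy = site.y_um - site.reference[1]
    dv_um = dx * np.sin(a) + dy * np.cos(a)
    return float(dv_um / 1000.0)


@dataclass
class BoundaryTable:
    """Region × gridline → (ventral_dv_mm, dorsal_dv_mm).

    ``entries[region][rc]`` holds full-precision extents; absent crossings
    are simply missing keys. ``decimals`` controls display rounding only.
    """

    gridlines: list[float]
    entries: dict[str, dict[float, tuple[float, float]]]
    decimals: int = 2
    meta: dict = field(default_factory=dict)

    def rounded(self, region: str, rc: float) -> tuple[float, float] | None:
        ent = self.entries.get(region, {}).get(rc)
        if ent is None:
            return None
        v, d = (round(x, self.decimals) for x in ent)
        if v >= d:
            # Tangent or sub-rounding-width crossing: no printable width.
            return None
        return (v, d)

    def to_tidy_frame(self) -> pd.DataFrame:
        rows = []
        for region, per_rc in self.entries.items():
            for rc in sorted(per_rc):
                r = self.rounded(region, rc)
                if r is None:
                    continue
                rows.append(
                    {"region": region, "rc_mm": rc, "ventral": r[0], "dorsal": r[1]}
                )
        return pd.DataFrame(rows, columns=["region", "rc_mm", "ventral", "dorsal"])

    def to_tidy_csv(self, path: str | Path) -> None:
        self.to_tidy_frame().to_csv(path, index=False)

    def to_tsv(self, path: str | Path | None = None) -> str:
        """Wide layout: rows = RC gridlines, a ventral/dorsal column pair
        per region, en dash for absent crossings."""
        regions = list(self.entries.keys())
        lines = ["\t" + "\t\t".join(regions)]
        lines.append("\t" + "\t".join(["ventral\tdorsal"] * len(regions)))
        fmt = f"{{:.{self.decimals}f}}"
        for rc in self.gridlines:
            cells = [f"{rc:.1f} mm"]
            for region in regions:
                r = self.rounded(region, rc)
                cells.extend(["–", "–"] if r is None else [fmt.format(r[0]), fmt.format(r[1])])
            lines.append("\t".join(cells))
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def occupied(self, region: str) -> list[float]:
        return sorted(rc for rc in self.entries.get(region, {}))


def gridline_boundaries(
    smap: SurfaceMap,
    rc_start: float = 2.0,
    rc_end: float = 4.0,
    step: float = 0.2,
    decimals: int = 2,
) -> BoundaryTable:
    """Intersect each region polygon with the vertical gridlines.

    For gridline rc = g crossing a region, ventral = min DV and dorsal =
    max DV of the intersection (the outermost extent for non-convex
    crossings). Tangent touches (zero width after rounding) are reported
    absent. Internal values keep full precision; rounding is display-only.
    """
    n = int(round((rc_end - rc_start) / step))
    gridlines = [round(rc_start + i * step, 10) for i in range(n + 1)]
    entries: dict[str, dict[float, tuple[float, float]]] = {}
    for region, poly in smap.regions.items():
        if poly.is_empty or poly.area == 0:
            raise ValueError(f"degenerate polygon for region {region}")
        minx, miny, maxx, maxy = poly.bounds
        per_rc: dict[float, tuple[float, float]] = {}
        for g in gridlines:
            line = LineString([(g, miny - 1.0), (g, maxy + 1.0)])
            hit = poly.intersection(line)
            if hit.is_empty:
                continue
            ys = [xy[1] for geom in getattr(hit, "geoms", [hit]) for xy in geom.coords]
            v, d = min(ys), max(ys)
            if d <= v:
                continue  # tangency
            per_rc[g] = (v, d)
        entries[region] = per_rc
    return BoundaryTable(
        gridlines,
        entries,
        decimals=decimals,
        meta={"rc_start": rc_start, "rc_end": rc_end, "step": step},
    )


def render_coronal_overlays(
    table: BoundaryTable,
    dv_range_mm: tuple[float, float] = (0.0, 2.5),
    px_per_mm: int = 100,
    out_dir: str | Path | None = None,
) -> dict[float, np.ndarray]:
    """Per-gridline schematic of the regions' DV spans.

    Returns one small label image per gridline (rows = DV from dorsal at
    the top, columns = one stripe per region; pixel value = 1 + region
    index inside that region's span, 0 elsewhere). If ``out_dir`` is
    given, a colored PNG per gridline is also written.
    """
    regions = list(table.entries.keys())
    dv_lo, dv_hi = dv_range_mm
    height = int(round((dv_hi - dv_lo) * px_per_mm))
    stripe = 20
    images: dict[float, np.ndarray] = {}
    for rc in table.gridlines:
        img = np.zeros((height, stripe * len(regions)), dtype=np.uint8)
        for i, region in enumerate(regions):
            ent = table.entries[region].get(rc)
            if ent is None:
                continue
            v, d = ent
            # row 0 = dorsal-most DV
            r0 = int(round((dv_hi - d) * px_per_mm))
            r1 = int(round((dv_hi - v) * px_per_mm))
            img[max(r0, 0) : min(r1, height), i * stripe : (i + 1) * stripe] = i + 1
        images[rc] = img
    if out_dir is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rc, img in images.items():
            fig, ax = plt.subplots(figsize=(2.5, 4))
            ax.imshow(img, cmap="tab10", vmin=0, vmax=9, interpolation="nearest")
            ax.set_xticks([stripe // 2 + i * stripe for i in range(len(regions))])
            ax.set_xticklabels(regions, fontsize=6, rotation=45)
            ax.set_ylabel(f"DV (dorsal at top), {px_per_mm} px/mm")
            ax.set_title(f"{rc:.1f} mm posterior to bregma", fontsize=8)
            fig.tight_layout()
            fig.savefig(out_dir / f"coronal_{rc:.1f}mm.png", dpi=120)
            plt.close(fig)
    return images
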