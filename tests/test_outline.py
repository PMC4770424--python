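"""Outline chain: threshold, island filter, upsampling, Sobel, polar profile."""

import numpy as np
import pytest

from tonomap.outline import (
    PolarOutline,
    RegionMask,
    binarize,
    extract_outline,
    largest_island,
    outline_center,
    polar_profile,
    sobel_edge,
    trim,
    upsample,
)
from tonomap.response import ResponseMap

from conftest import disk_response_map


def sobel_oracle(mask: np.ndarray) -> np.ndarray:
    """Brute-force nested-loop convolution of the two 3×3 kernels with
    reflected boundary indices; edge = nonzero RMS magnitude."""
    kh = [[1, 2, 1], [0, 0, 0], [-1, -2, -1]]
    mask = mask.astype(int)
    h, w = mask.shape

    def ref(i, n):
        if i < 0:
            return -i - 1
        if i >= n:
            return 2 * n - i - 1
        return i

    edges = []
    for r in range(h):
        for c in range(w):
            gh = gv = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    v = mask[ref(r + dr, h), ref(c + dc, w)]
                    gh += kh[1 + dr][1 + dc] * v
                    gv += kh[1 + dc][1 + dr] * v
            if np.sqrt(gh**2 + gv**2) > 0:
                edges.append((r, c))
    return np.array(edges).reshape(-1, 2)


def flood_fill_largest(mask: np.ndarray) -> np.ndarray:
    """Independent BFS flood-fill oracle for the largest 8-connected
    component (scan-order tie break)."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    best = None
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = []
                queue = [(r, c)]
                seen[r, c] = True
                while queue:
                    rr, cc = queue.pop()
                    comp.append((rr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                                seen[nr, nc] = True
                                queue.append((nr, nc))
                if best is None or len(comp) > len(best):
                    best = comp
    out = np.zeros_like(mask)
    for rr, cc in best:
        out[rr, cc] = 1
    return out


class TestTrim:
    def test_full_bbox_identity(self):
        m = ResponseMap(np.arange(20.0).reshape(4, 5), 20.4)
        out = trim(m, (0, 4, 0, 5))
        assert np.array_equal(out.values, m.values) and out.origin == (0, 0)

    def test_offset_bookkeeping_round_trip(self):
        m = ResponseMap(np.random.default_rng(0).normal(size=(30, 30)), 20.4)
        out = trim(m, (10, 20, 5, 15))
        assert out.values.shape == (10, 10)
        assert out.origin == (10, 5)
        # un-trim: placing back at the origin reproduces the crop site
        assert np.array_equal(
            m.values[out.origin[0] : out.origin[0] + 10, out.origin[1] : out.origin[1] + 10],
            out.values,
        )

    def test_empty_bbox_rejected(self):
        m = ResponseMap(np.ones((5, 5)), 20.4)
        with pytest.raises(ValueError):
            trim(m, (3, 3, 0, 5))


class TestBinarize:
    def test_strict_threshold(self):
        v = np.array([[1.0, 0.61, 0.59], [0.60, 0.0, 0.2]])
        mask = binarize(ResponseMap(v, 20.4), frac=0.6).values
        assert mask.tolist() == [[1, 1, 0], [0, 0, 0]]

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError):
            binarize(ResponseMap(np.full((3, 3), -1.0), 20.4))

    def test_level_set_radius_of_raised_cosine(self):
        """For a radially decreasing raised-cosine blob the mask is a disk
        whose radius matches the analytic 60% level set within 1 px."""
        shape = (61, 61)
        rows = np.arange(shape[0])[:, None]
        cols = np.arange(shape[1])[None, :]
        r = np.hypot(rows - 30, cols - 30)
        r_zero = 25.0
        v = 0.5 * (1 + np.cos(np.pi * np.clip(r / r_zero, 0, 1)))
        mask = binarize(ResponseMap(v, 20.4)).values
        r60 = r_zero * np.arccos(0.2) / np.pi  # analytic inverse
        radii = r[mask == 1]
        assert radii.max() <= r60 + 1.0
        # every pixel strictly inside r60 - 1 is foreground
        assert np.all(mask[(r < r60 - 1.0)] == 1)


class TestLargestIsland:
    def test_speck_removed(self):
        m = np.zeros((20, 20), dtype=np.uint8)
        m[2:9, 2:9] = 1  # 49 px blob
        m[15, 15] = m[15, 16] = 1  # 2 px speck
        out = largest_island(RegionMask(m, 20.4)).values
        assert out.sum() == 49 and out[15, 15] == 0

    def test_single_component_unchanged(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[3:7, 3:7] = 1
        assert np.array_equal(largest_island(RegionMask(m, 20.4)).values, m)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            largest_island(RegionMask(np.zeros((5, 5), dtype=np.uint8), 20.4))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((18, 18)) < 0.35).astype(np.uint8)
        if m.sum() == 0:
            m[0, 0] = 1
        out = largest_island(RegionMask(m, 20.4)).values
        assert np.array_equal(out, flood_fill_largest(m))


class TestUpsample:
    def test_block_structure_and_count(self):
        m = (np.random.default_rng(1).random((3, 3)) < 0.5).astype(np.uint8)
        up = upsample(RegionMask(m, 20.4), 50, 50)
        assert up.values.shape == (150, 150)
        assert up.values.sum() == m.sum() * 2500
        assert up.pixel_pitch_um == pytest.approx(20.4 / 50)
        # area in μm² conserved exactly
        assert up.values.sum() * up.pixel_pitch_um**2 == pytest.approx(
            m.sum() * 20.4**2
        )
        # block structure: every 50×50 block is constant
        blocks = up.values.reshape(3, 50, 3, 50)
        assert np.all(blocks.min(axis=(1, 3)) == blocks.max(axis=(1, 3)))

    def test_anisotropic_rejected(self):
        with pytest.raises(ValueError):
            upsample(RegionMask(np.ones((2, 2), dtype=np.uint8), 20.4), 50, 25)


class TestSobelEdge:
    def test_uniform_masks_have_no_edges(self):
        for fill in (0, 1):
            m = RegionMask(np.full((10, 10), fill, dtype=np.uint8), 20.4)
            assert len(sobel_edge(m)) == 0

    def test_half_plane_step_band(self):
        """A horizontal step yields |gv| = 4 on the two flanking rows and
        gh = 0 (hand convolution of the stated kernels)."""
        m = np.zeros((10, 10), dtype=np.uint8)
        m[5:] = 1
        edges = sobel_edge(RegionMask(m, 20.4))
        rows = set(edges[:, 0])
        assert rows == {4, 5}
        assert len(edges) == 20  # full two-row band

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = (rng.random((16, 16)) < 0.5).astype(np.uint8)
        ours = {tuple(e) for e in sobel_edge(RegionMask(m, 20.4))}
        oracle = {tuple(e) for e in sobel_oracle(m)}
        assert ours == oracle


class TestOutlineCenter:
    def test_four_corners(self):
        assert outline_center(np.array([[0, 0], [0, 2], [2, 0], [2, 2]])) == (1.0, 1.0)

    def test_translation_equivariance(self):
        pts = np.random.default_rng(2).integers(0, 50, (30, 2))
        c0 = outline_center(pts)
        c1 = outline_center(pts + [7, 11])
        assert c1 == (c0[0] + 7, c0[1] + 11)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            outline_center(np.empty((0, 2)))


def digital_circle_edges(radius: float, center=(0.0, 0.0), n=4096):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack(
        [center[0] + radius * np.sin(th), center[1] + radius * np.cos(th)]
    )
    return np.round(pts).astype(int)


class TestPolarProfile:
    def test_circle_profile(self):
        edges = digital_circle_edges(200.0, center=(300, 300))
        prof = polar_profile(edges, (300.0, 300.0))
        assert prof.distances.size == 7200
        assert np.all(np.abs(prof.distances - 200.0) <= 1.0)

    def test_ellipse_axes(self):
        """Rendered ellipse mask: d(0°) ≈ semi-major, d(90°) ≈ semi-minor."""
        rows = np.arange(401)[:, None]
        cols = np.arange(401)[None, :]
        a, b = 150.0, 90.0
        inside = (((cols - 200) / a) ** 2 + ((rows - 200) / b) ** 2) < 1.0
        mask = RegionMask(inside.astype(np.uint8), 20.4)
        edges = sobel_edge(mask)
        c = outline_center(edges)
        prof = polar_profile(edges, c)
        assert prof.distances[0] == pytest.approx(a, abs=2.0)
        assert prof.distances[1800] == pytest.approx(b, abs=2.0)  # 90°

    def test_rotation_by_90_degrees_shifts_bins(self):
        rng = np.random.default_rng(3)
        mask = np.zeros((41, 41), dtype=np.uint8)
        rr, cc = np.ogrid[:41, :41]
        blob = ((rr - 20) ** 2 / 120 + (cc - 20) ** 2 / 260) < 1
        mask[blob] = 1
        m0 = RegionMask(mask, 20.4)
        m90 = RegionMask(np.rot90(mask).copy(), 20.4)
        e0, e90 = sobel_edge(m0), sobel_edge(m90)
        p0 = polar_profile(e0, outline_center(e0))
        p90 = polar_profile(e90, outline_center(e90))
        # rot90 maps (r, c) → (n-1-c, r): θ' = θ + 90°, i.e. 1800 bins
        shifted = np.roll(p0.distances, 1800)
        assert np.allclose(shifted, p90.distances, atol=0.6)

    def test_center_outside_hull_rejected(self):
        edges = digital_circle_edges(50.0, center=(100, 100))
        with pytest.raises(ValueError, match="convex hull"):
            polar_profile(edges, (300.0, 300.0))

    def test_empty_bins_interpolated(self):
        # only 4 edge pixels: most of the 7200 bins are interpolated
        prof = polar_profile(
            np.array([[0, 10], [0, -10], [10, 0], [-10, 0]]), (0.0, 0.0)
        )
        assert prof.distances.size == 7200
        assert np.all(prof.distances > 0)


class TestExtractOutlineEndToEnd:
    def test_disk_recovery_native_pitch(self):
        """At the camera pitch (20.4 μm) the chain recovers a 150-μm disk
        outline to the native-pixel quantization bound (≤ 1 px: the
        contour is binarized on the native grid before the 50× density
        increase) and its center to within one original pixel."""
        rmap, center_px = disk_response_map(radius_um=150.0, pitch_um=20.4)
        prof = extract_outline(rmap)
        assert np.all(np.abs(prof.distances - 150.0) <= 1.0 * 20.4)
        err_px = np.hypot(prof.center[0] - center_px[0], prof.center[1] - center_px[1])
        assert err_px <= 1.0

    def test_translation_equivariance_and_scale_invariance(self):
        rmap, _ = disk_response_map(radius_um=150.0, pitch_um=20.4, shape=(64, 64))
        shifted = ResponseMap(np.roll(rmap.values, (3, 5), axis=(0, 1)), 20.4)
        p0 = extract_outline(rmap)
        p1 = extract_outline(shifted)
        p2 = extract_outline(ResponseMap(rmap.values * 17.3, 20.4))
        assert p1.center[0] == pytest.approx(p0.center[0] + 3, abs=1e-6)
        assert p1.center[1] == pytest.approx(p0.center[1] + 5, abs=1e-6)
        assert np.allclose(p0.distances, p1.distances)
        assert np.array_equal(p0.distances, p2.distances)

    def test_units_are_micrometres(self):
        rmap, _ = disk_response_map(radius_um=150.0, pitch_um=20.4)
        prof = extract_outline(rmap)
        assert prof.unit == "um"
        assert prof.distances.mean() == pytest.approx(150.0, rel=0.05)


class TestPolarOutlineContainer:
    def test_json_round_trip(self, tmp_path):
        prof = PolarOutline(
            np.arange(72) * 5.0, np.full(72, 0.15), "mm", center=(2.5, 1.2), n_subjects=5
        )
        path = tmp_path / "outline.json"
        prof.to_json(path)
        back = PolarOutline.from_json(path)
        assert np.array_equal(back.distances, prof.distances)
        assert back.unit == "mm" and back.center == (2.5, 1.2)

    def test_validation(self):
        with pytest.raises(ValueError):
            PolarOutline(np.array([0.0, 0.0, 1.0]), np.ones(3), "mm")
        with pytest.raises(ValueError):
            PolarOutline(np.arange(3.0), np.array([1.0, -1.0, 1.0]), "mm")
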