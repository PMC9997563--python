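"""Silhouette detection: background model, binarization, labeling, size filter."""

from collections import deque

import numpy as np
import pytest

from flywell.detect import (
    Component,
    DetectorParams,
    binarize_well,
    detect_session,
    estimate_background,
    label_components,
    select_fly,
    to_grayscale,
    well_mask,
)


def flood_fill_components(mask, connectivity):
    """Independent BFS flood-fill oracle returning (area, centroid, pixels)
    per component; pixels as (x, y)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                q = deque([(r, c)])
                seen[r, c] = True
                pix = []
                while q:
                    y, x = q.popleft()
                    pix.append((x, y))
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            q.append((ny, nx))
                xs = [p[0] for p in pix]
                ys = [p[1] for p in pix]
                comps.append((len(pix), (np.mean(xs), np.mean(ys)), frozenset(pix)))
    return comps


class TestEstimateBackground:
    def test_identical_frames_give_that_frame(self, small_layout, rng):
        well = small_layout.wells["A1"]
        frame = rng.integers(0, 255, (small_layout.frame_height, small_layout.frame_width))
        bg = estimate_background([frame] * 5, well)
        crop_bg = estimate_background([frame] * 3, well)
        assert np.array_equal(bg, crop_bg)

    def test_median_ignores_minority_occlusion(self, small_layout):
        well = small_layout.wells["A1"]
        shape = (small_layout.frame_height, small_layout.frame_width)
        clean = np.full(shape, 200.0)
        occluded = clean.copy()
        occluded[10:14, 10:14] = 50.0  # blob present in 2 of 5 frames
        bg = estimate_background([clean, clean, clean, occluded, occluded], well)
        assert (bg == 200.0).all()

    def test_matches_sort_and_middle_oracle(self, small_layout, rng):
        well = small_layout.wells["A1"]
        shape = (small_layout.frame_height, small_layout.frame_width)
        frames = [rng.integers(0, 255, shape).astype(float) for _ in range(7)]
        bg = estimate_background(frames, well)
        # brute-force per-pixel sort-and-middle over the same bbox
        xs = [int(p.x) for p in well.corners]
        ys = [int(p.y) for p in well.corners]
        x0, y0 = min(xs), min(ys)
        for _ in range(50):
            r = int(rng.integers(0, bg.shape[0]))
            c = int(rng.integers(0, bg.shape[1]))
            vals = sorted(f[y0 + r, x0 + c] for f in frames)
            assert bg[r, c] == vals[len(vals) // 2]

    def test_too_few_frames_rejected(self, small_layout):
        shape = (small_layout.frame_height, small_layout.frame_width)
        with pytest.raises(ValueError, match=">= 3"):
            estimate_background([np.zeros(shape)] * 2, small_layout.wells["A1"])


class TestBinarizeWell:
    def test_frame_equal_to_background_is_empty(self, small_layout):
        well = small_layout.wells["A1"]
        shape = (small_layout.frame_height, small_layout.frame_width)
        frame = np.full(shape, 180.0)
        bg = estimate_background([frame] * 3, well)
        assert not binarize_well(frame, well, bg, delta=25.0).any()

    def test_exact_pixel_count_for_constructed_darkening(self, small_layout):
        well = small_layout.wells["A1"]
        shape = (small_layout.frame_height, small_layout.frame_width)
        base = np.full(shape, 200.0)
        bg = estimate_background([base] * 3, well)
        frame = base.copy()
        # 40 pixels darkened by 2*delta, well inside the polygon
        ys, xs = np.meshgrid(np.arange(40, 45), np.arange(40, 48), indexing="ij")
        frame[ys, xs] = 200.0 - 50.0
        mask = binarize_well(frame, well, bg, delta=25.0)
        assert int(mask.sum()) == 40

    def test_boundary_intensity_stays_background(self, small_layout):
        well = small_layout.wells["A1"]
        shape = (small_layout.frame_height, small_layout.frame_width)
        base = np.full(shape, 200.0)
        bg = estimate_background([base] * 3, well)
        frame = base.copy()
        frame[40, 40] = 175.0  # exactly background - delta: strict inequality
        assert not binarize_well(frame, well, bg, delta=25.0).any()
        frame[40, 40] = 174.0
        assert int(binarize_well(frame, well, bg, delta=25.0).sum()) == 1

    def test_pixels_outside_polygon_never_foreground(self, small_layout):
        well = small_layout.wells["A1"]
        shape = (small_layout.frame_height, small_layout.frame_width)
        base = np.full(shape, 200.0)
        bg = estimate_background([base] * 3, well)
        frame = np.zeros(shape)  # everything maximally dark
        mask = binarize_well(frame, well, bg, delta=25.0)
        assert np.array_equal(mask, well_mask(well, shape))

    def test_negative_delta_rejected(self, small_layout):
        well = small_layout.wells["A1"]
        shape = (small_layout.frame_height, small_layout.frame_width)
        base = np.full(shape, 200.0)
        bg = estimate_background([base] * 3, well)
        with pytest.raises(ValueError, match="delta"):
            binarize_well(base, well, bg, delta=-1.0)


class TestLabelComponents:
    def test_single_pixel(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[7, 5] = True  # row 7 = y, col 5 = x
        comps = label_components(mask, 8)
        assert len(comps) == 1
        assert comps[0].area_px == 1
        assert (comps[0].centroid.x, comps[0].centroid.y) == (5.0, 7.0)

    def test_diagonal_contact_depends_on_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(label_components(mask, 8)) == 1
        assert len(label_components(mask, 4)) == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_on_random_masks(self, connectivity, rng):
        for _ in range(200):
            mask = rng.random((16, 16)) < 0.35
            got = sorted(
                (c.area_px, c.pixel_set) for c in label_components(mask, connectivity)
            )
            want = sorted((a, pix) for a, _, pix in flood_fill_components(mask, connectivity))
            assert got == want
            # centroids too
            got_c = {c.pixel_set: (c.centroid.x, c.centroid.y) for c in label_components(mask, connectivity)}
            for a, (cx, cy), pix in flood_fill_components(mask, connectivity):
                assert got_c[pix] == pytest.approx((cx, cy))

    def test_area_conservation(self, rng):
        for _ in range(50):
            mask = rng.random((20, 20)) < 0.4
            comps = label_components(mask, 8)
            assert sum(c.area_px for c in comps) == int(mask.sum())

    def test_origin_offset_shifts_coordinates(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        (c,) = label_components(mask, 8, origin=(100, 50))
        assert (c.centroid.x, c.centroid.y) == (103.0, 52.0)


class TestSelectFly:
    def comp(self, pixels):
        return Component.from_pixels(pixels)

    def test_largest_above_threshold_selected(self):
        comps = [
            self.comp([(0, 0), (1, 0), (2, 0), (3, 0), (4, 0)]),
            self.comp([(i, 5) for i in range(9)]),
            self.comp([(0, 9), (1, 9), (2, 9)]),
        ]
        assert select_fly(comps, min_area=4).area_px == 9

    def test_all_below_threshold_gives_none(self):
        comps = [self.comp([(0, 0), (1, 0)]), self.comp([(5, 5)])]
        assert select_fly(comps, min_area=8) is None
        assert select_fly([], min_area=8) is None

    def test_tie_breaks_to_first_top_left_pixel_in_row_major_order(self):
        a = self.comp([(5, 2), (6, 2)])  # top-left pixel (y=2, x=5)
        b = self.comp([(1, 3), (2, 3)])  # top-left pixel (y=3, x=1)
        assert select_fly([b, a], min_area=1) is a
        assert select_fly([a, b], min_area=1) is a


class TestDetectSession:
    def test_deterministic_on_identical_frames(self, small_session):
        sub = small_session.frames[:30]
        r1 = detect_session(sub, small_session.layout)
        r2 = detect_session(sub, small_session.layout)
        assert r1 == r2

    def test_found_false_when_no_fly(self, small_layout):
        shape = (small_layout.frame_height, small_layout.frame_width)
        blank = np.full(shape, 200, dtype=np.uint8)
        recs = detect_session([blank] * 5, small_layout)
        assert all(not r.found for rr in recs.values() for r in rr)

    def test_min_area_filters_specks_but_not_fly(self, small_session):
        params = DetectorParams(min_area=8)
        recs = detect_session(small_session.frames[:60], small_session.layout, params)
        for wid, rr in recs.items():
            for r in rr:
                assert r.found
                assert r.area_px >= params.min_area

    def test_grayscale_conversion_handles_rgb(self):
        rgb = np.zeros((4, 4, 3), dtype=np.uint8)
        rgb[..., 1] = 255
        g = to_grayscale(rgb)
        assert g.shape == (4, 4)
        assert g[0, 0] == pytest.approx(0.587 * 255)
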