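import numpy as np
import pytest

from conftest import disk_mask, random_mask
from vertfract import phantom, preprocess
from vertfract.segment import (
    SegmentConfig, StructuringElement, binarize, clear_border, closing,
    convex_hull_regions, dilate, erode, fill_holes, filter_components,
    label_vertebrae, opening, segment_pipeline,
)


def se_offsets(se: StructuringElement) -> np.ndarray:
    """(dy, dx) offsets of the structuring element relative to its origin."""
    fp = se.footprint()
    r = fp.shape[0] // 2
    ys, xs = np.nonzero(fp)
    return np.column_stack([ys - r, xs - r])


def brute_dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Set-definition oracle: z is kept iff the reflected SE at z hits A."""
    offs = -se_offsets(se)          # reflection of B
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            for dy, dx in offs:
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w and mask[yy, xx]:
                    out[y, x] = True
                    break
    return out


def brute_erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Fit-condition oracle: z kept iff (B)_z lies entirely in A
    (out-of-image pixels count as background)."""
    offs = se_offsets(se)
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            ok = True
            for dy, dx in offs:
                yy, xx = y + dy, x + dx
                if not (0 <= yy < h and 0 <= xx < w and mask[yy, xx]):
                    ok = False
                    break
            out[y, x] = ok
    return out


SES = [StructuringElement("square", 1), StructuringElement("disk", 1),
       StructuringElement("disk", 2), StructuringElement("square", 2)]


class TestMorphology:
    def test_single_pixel_dilates_to_block(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        out = dilate(m, StructuringElement("square", 1))
        assert out.sum() == 9 and out[1:4, 1:4].all()

    def test_empty_mask_stays_empty(self):
        m = np.zeros((6, 6), dtype=bool)
        assert not dilate(m, StructuringElement("disk", 2)).any()

    def test_block_erodes_to_center(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1:4, 1:4] = True
        out = erode(m, StructuringElement("square", 1))
        assert out.sum() == 1 and out[2, 2]

    def test_full_mask_erosion_removes_border_band(self):
        m = np.ones((9, 9), dtype=bool)
        out = erode(m, StructuringElement("square", 2))
        assert np.array_equal(out, brute_erode(m, StructuringElement("square", 2)))
        assert out.sum() == 5 * 5

    @pytest.mark.parametrize("se", SES, ids=lambda s: f"{s.shape}{s.radius}")
    def test_matches_set_definition_oracle(self, se, rng):
        for shape in [(7, 9), (12, 12), (9, 9)]:
            for _ in range(6):
                m = random_mask(rng, shape, p=rng.uniform(0.1, 0.7))
                assert np.array_equal(dilate(m, se), brute_dilate(m, se))
                assert np.array_equal(erode(m, se), brute_erode(m, se))

    def test_erosion_dilation_duality(self, rng):
        se = StructuringElement("disk", 2)
        for _ in range(10):
            m = random_mask(rng, (16, 16), p=0.5)
            # erode(A) = NOT dilate(NOT A) when out-of-image counts as
            # background for A (i.e. foreground for its complement)
            assert np.array_equal(brute_erode(m, se), erode(m, se))
            dual = ~dilate(np.pad(~m, 2, constant_values=True), se)[2:-2, 2:-2]
            assert np.array_equal(erode(m, se), dual)

    def test_closing_extensive_and_idempotent(self, rng):
        se = StructuringElement("disk", 2)
        for _ in range(5):
            m = random_mask(rng, (20, 20), p=0.3)
            c1 = closing(m, se)
            assert (c1 | m).sum() == c1.sum()           # extensive
            assert np.array_equal(closing(c1, se), c1)  # idempotent

    def test_opening_antiextensive_and_idempotent(self, rng):
        se = StructuringElement("disk", 1)
        for _ in range(5):
            m = random_mask(rng, (20, 20), p=0.6)
            o1 = opening(m, se)
            assert (o1 & m).sum() == o1.sum()           # anti-extensive
            assert np.array_equal(opening(o1, se), o1)  # idempotent


class TestBinarize:
    def test_fixed_threshold(self):
        img = np.array([[50, 150], [150, 50]], dtype=np.uint8)
        assert np.array_equal(binarize(img, "fixed", 100), [[0, 1], [1, 0]])

    def test_otsu_two_valued(self):
        img = np.where(np.arange(64).reshape(8, 8) < 32, 40, 200).astype(np.uint8)
        out = binarize(img, "otsu")
        assert np.array_equal(out, img == 200)

    def test_fixed_255_empty(self):
        img = np.full((4, 4), 254, dtype=np.uint8)
        assert not binarize(img, "fixed", 255).any()

    def test_constant_image_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            binarize(np.full((4, 4), 7, dtype=np.uint8), "otsu")


class TestRegionOps:
    def test_fill_holes_annulus(self):
        m = disk_mask(8) & ~disk_mask(4, pad=7)
        assert np.array_equal(fill_holes(m), disk_mask(8))

    def test_fill_holes_no_holes_unchanged(self):
        m = disk_mask(5)
        assert np.array_equal(fill_holes(m), m)

    def test_fill_holes_nested_rings(self):
        # flood-fill-from-border oracle: everything inside the outer ring fills
        n = 41
        yy, xx = np.mgrid[0:n, 0:n]
        r2 = (yy - 20) ** 2 + (xx - 20) ** 2
        m = ((r2 <= 18**2) & (r2 >= 15**2)) | ((r2 <= 10**2) & (r2 >= 7**2))
        assert np.array_equal(fill_holes(m), r2 <= 18**2)

    def test_clear_border(self):
        m = np.zeros((10, 10), dtype=bool)
        m[0, 3:6] = True          # touches top
        m[4:6, 4:6] = True        # interior
        m[7:, 8:] = True          # touches corner
        out = clear_border(m)
        expect = np.zeros_like(m)
        expect[4:6, 4:6] = True
        assert np.array_equal(out, expect)

    def test_filter_components_drops_speck_and_far_blob(self):
        m = np.zeros((40, 100), dtype=bool)
        for i in range(5):
            m[i * 8:i * 8 + 5, 45:55] = True     # aligned column of blobs
        m[0:2, 0:1] = True                       # 2-px speck
        m[30:35, 90:98] = True                   # far-right blob
        out = filter_components(m, min_area_fraction=0.1, centroid_band_fraction=0.15)
        assert not out[0:2, 0:1].any()
        assert not out[30:35, 90:98].any()
        assert out[:, 45:55].sum() == 5 * 5 * 10

    def test_filter_single_component_kept(self):
        m = np.zeros((20, 20), dtype=bool)
        m[3:8, 15:19] = True
        assert np.array_equal(filter_components(m, 0.5, 0.01), m)

    def test_filter_empty_raises(self):
        with pytest.raises(ValueError, match="no components"):
            filter_components(np.zeros((5, 5), dtype=bool))


def in_hull_oracle(points: np.ndarray, q: np.ndarray) -> bool:
    """q is a convex combination of points iff it lies in some triangle
    (Caratheodory in the plane); degenerate triangles are handled by the
    segment/point checks below."""
    pts = points.astype(float)
    n = len(pts)
    if any(np.array_equal(q, p) for p in pts):
        return True

    def on_segment(a, b):
        ab, aq = b - a, q - a
        cross = ab[0] * aq[1] - ab[1] * aq[0]
        if cross != 0:
            return False
        t = np.dot(aq, ab)
        return 0 <= t <= np.dot(ab, ab)

    def in_triangle(a, b, c):
        area2 = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
        if area2 == 0:
            return False    # degenerate: covered by the segment checks
        d1 = (q[0] - b[0]) * (a[1] - b[1]) - (a[0] - b[0]) * (q[1] - b[1])
        d2 = (q[0] - c[0]) * (b[1] - c[1]) - (b[0] - c[0]) * (q[1] - c[1])
        d3 = (q[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (q[1] - a[1])
        neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
        pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
        return not (neg and pos)

    for i in range(n):
        for j in range(i + 1, n):
            if on_segment(pts[i], pts[j]):
                return True
            for k in range(j + 1, n):
                if in_triangle(pts[i], pts[j], pts[k]):
                    return True
    return False


class TestConvexHull:
    def test_solid_rectangle_unchanged(self):
        m = np.zeros((12, 12), dtype=bool)
        m[2:9, 3:10] = True
        assert np.array_equal(convex_hull_regions(m), m)

    def test_notch_filled_matches_membership_oracle(self):
        m = np.zeros((14, 14), dtype=bool)
        m[2:12, 2:12] = True
        m[2:7, 7:12] = False     # notched corner
        out = convex_hull_regions(m)
        pts = np.column_stack(np.nonzero(m))
        expect = np.zeros_like(m)
        for y in range(14):
            for x in range(14):
                expect[y, x] = in_hull_oracle(pts, np.array([y, x]))
        assert np.array_equal(out, expect)

    def test_sparse_points_match_membership_oracle(self, rng):
        m = np.zeros((18, 18), dtype=bool)
        idx = rng.choice(18 * 18, size=12, replace=False)
        m.flat[idx] = True
        out = convex_hull_regions(m)
        # Eq.-4 membership oracle evaluated per 8-connected component
        from skimage import measure
        lab = measure.label(m, connectivity=2)
        expect = np.zeros_like(m)
        for lbl in range(1, lab.max() + 1):
            cpts = np.column_stack(np.nonzero(lab == lbl))
            for y in range(18):
                for x in range(18):
                    if in_hull_oracle(cpts, np.array([y, x])):
                        expect[y, x] = True
        assert np.array_equal(out, expect)

    def test_hull_never_shrinks(self, rng):
        for _ in range(5):
            m = random_mask(rng, (15, 15), p=0.2)
            if not m.any():
                continue
            out = convex_hull_regions(m)
            assert (out & m).sum() == m.sum()


class TestLabeling:
    def test_five_stacked_blobs_labeled_top_down(self):
        m = np.zeros((60, 20), dtype=bool)
        for i in range(5):
            m[i * 12 + 2:i * 12 + 8, 5:15] = True
        regions, warning = label_vertebrae(m, expected_n=5)
        assert not warning
        assert [r.level for r in regions] == ["L1", "L2", "L3", "L4", "L5"]
        assert all(regions[i].centroid[1] < regions[i + 1].centroid[1] for i in range(4))

    def test_count_mismatch_warns(self):
        m = np.zeros((40, 20), dtype=bool)
        for i in range(3):
            m[i * 12 + 2:i * 12 + 8, 5:15] = True
        regions, warning = label_vertebrae(m, expected_n=5)
        assert warning and [r.level for r in regions] == ["L1", "L2", "L3"]

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            label_vertebrae(np.zeros((5, 5), dtype=bool))

    def test_contour_starts_topmost_leftmost_and_is_clockwise(self):
        m = np.zeros((10, 10), dtype=bool)
        m[3:7, 2:8] = True
        regions, _ = label_vertebrae(m, expected_n=1)
        c = regions[0].contour
        assert c[0, 1] == c[:, 1].min()                       # topmost y
        x, y = c[:, 0], c[:, 1]
        shoelace = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert shoelace < 0                                   # clockwise, y down


class TestPipeline:
    def test_noise_free_phantom_recovers_centroids_and_dice(self, clean_case):
        from vertfract.evaluate import dice
        smoothed = preprocess.spatial_filter(clean_case.image, "median3")
        regions, warning = segment_pipeline(smoothed, SegmentConfig())
        assert not warning and len(regions) == 5
        for r, tm in zip(regions, clean_case.truth_masks):
            ys, xs = np.nonzero(tm)
            assert abs(r.centroid[0] - xs.mean()) < 2
            assert abs(r.centroid[1] - ys.mean()) < 2
            assert dice(r.mask, tm) >= 99.0

    def test_stage_log_emitted(self, small_case):
        log = []
        segment_pipeline(preprocess.spatial_filter(small_case.image, "median3"),
                         SegmentConfig(), log=log)
        assert [e["stage"] for e in log] == [
            "binarize", "closing", "fill_holes", "clear_border",
            "filter_components", "convex_hull"]
        assert all(e["n_components"] >= 1 for e in log)
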