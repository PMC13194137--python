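"""Silhouette filling, width profiles, boundary finding and the row partition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk as draw_disk

from baumtest.errors import NoDrawingError
from baumtest.ink_extraction import ComponentMask
from baumtest.pipeline import measure_image
from baumtest.segmentation import (
    LOW_CONFIDENCE_CROWN,
    Boundaries,
    fill_silhouette,
    find_boundaries,
    segment_silhouette,
    segment_tree,
    width_profile,
)


def solid_disc(shape, center, radius):
    m = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius, shape=shape)
    m[rr, cc] = True
    return m


def lollipop(shape=(700, 400), radius=100, trunk_w=30, trunk_bottom=550):
    """Disc tangent on a rectangle; returns (mask, junction_row)."""
    m = solid_disc(shape, (150, 200), radius)
    junction = 150 + radius
    m[junction : trunk_bottom, 200 - trunk_w // 2 : 200 + trunk_w // 2] = True
    return m, junction


class TestFillSilhouette:
    def test_solid_disc_unchanged(self):
        m = solid_disc((200, 200), (100, 100), 50)
        filled = fill_silhouette(ComponentMask.from_mask(m), closing_radius_px=0)
        assert np.array_equal(filled, m)

    def test_circle_outline_becomes_solid_disc(self):
        outer = solid_disc((300, 300), (150, 150), 80)
        inner = solid_disc((300, 300), (150, 150), 78)
        ring = outer & ~inner  # 2-px stroke
        filled = fill_silhouette(ComponentMask.from_mask(ring), closing_radius_px=2)
        # area within one closing radius of the outer disc's
        assert filled.sum() == pytest.approx(outer.sum(), rel=0.05)
        assert not ndlabel_holes(filled)

    def test_outline_tree_filled_area_close_to_truth(self, noisy_render):
        spec, image, seg, _ = noisy_render
        from baumtest.ink_extraction import binarize, clean_mask, largest_component

        comp = largest_component(clean_mask(binarize(image), min_speck_px=6))
        filled = fill_silhouette(comp, closing_radius_px=3)
        assert filled.sum() == pytest.approx(seg.silhouette_mask.sum(), rel=0.05)


def ndlabel_holes(mask) -> bool:
    from scipy import ndimage

    return bool((ndimage.binary_fill_holes(mask) ^ mask).any())


class TestWidthProfile:
    def test_rectangle_has_constant_extent(self):
        m = np.zeros((100, 80), dtype=bool)
        m[20:70, 10:40] = True
        prof = width_profile(m)
        assert (prof.extents == 30).all()
        assert len(prof) == 50 and prof.top_row == 20

    def test_disc_center_extent_is_diameter(self):
        m = solid_disc((200, 200), (100, 100), 60)
        prof = width_profile(m)
        assert abs(int(prof.extents.max()) - 120) <= 2

    def test_empty_silhouette_rejected(self):
        with pytest.raises(NoDrawingError):
            width_profile(np.zeros((10, 10), dtype=bool))

    def test_smoothing_window_is_odd(self):
        m = np.zeros((400, 80), dtype=bool)
        m[10:390, 20:60] = True
        assert width_profile(m).smooth_window % 2 == 1


class TestFindBoundaries:
    def test_lollipop_junction_within_six_rows(self):
        m, junction = lollipop()
        b = find_boundaries(width_profile(m), alpha=0.5, run_rows=5)
        assert abs(b.crown_trunk_row - junction) <= 6

    def test_rectangle_only_falls_back_with_flag(self):
        m = np.zeros((300, 100), dtype=bool)
        m[20:280, 30:70] = True
        b = find_boundaries(width_profile(m))
        assert LOW_CONFIDENCE_CROWN in b.flags
        assert b.crown_trunk_row == 20  # top row: no crown identified

    def test_root_flare_onset_within_six_rows(self):
        m = solid_disc((700, 400), (150, 200), 90)
        m[238:500, 185:215] = True
        flare_top = 500
        for i in range(60):  # widen 30 px -> 75 px (2.5x trunk width)
            half = 15 + i * 22.5 / 60
            m[flare_top + i, int(200 - half) : int(200 + half)] = True
        b = find_boundaries(width_profile(m), beta=1.6)
        assert abs(b.trunk_root_row - flare_top) <= 6

    def test_no_flare_gives_no_roots_sentinel(self):
        m, _ = lollipop()
        prof = width_profile(m)
        b = find_boundaries(prof)
        assert b.trunk_root_row == prof.bottom_row + 1


class TestSegmentTree:
    def test_partition_identity_lollipop(self):
        m, junction = lollipop()
        seg = segment_tree(m, Boundaries(junction, 500))
        seg.validate()
        total = seg.crown_mask.sum() + seg.trunk_mask.sum() + seg.root_mask.sum()
        assert total == m.sum()

    def test_crown_pixels_match_disc_count(self):
        m, junction = lollipop()
        disc = solid_disc((700, 400), (150, 200), 100)
        seg = segment_tree(m, Boundaries(junction, 700))
        # crown = disc minus any disc rows at/below the junction
        assert seg.crown_mask.sum() == disc[:junction].sum()

    def test_no_roots_sentinel_empty_root_mask(self):
        m, junction = lollipop()
        seg = segment_tree(m, Boundaries(junction, m.shape[0]))
        assert seg.root_mask.sum() == 0

    def test_inverted_boundaries_rejected(self):
        m, _ = lollipop()
        with pytest.raises(ValueError):
            segment_tree(m, Boundaries(300, 200))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        radius=st.integers(30, 90),
        trunk_w=st.integers(8, 40),
        trunk_len=st.integers(50, 300),
    )
    def test_partition_identity_property(self, radius, trunk_w, trunk_len):
        m, _ = lollipop(shape=(700, 400), radius=radius, trunk_w=trunk_w,
                        trunk_bottom=150 + radius + trunk_len)
        seg = segment_silhouette(m)
        seg.validate()
        assert (
            seg.crown_mask.sum() + seg.trunk_mask.sum() + seg.root_mask.sum() == m.sum()
        )


class TestEquivariance:
    def test_horizontal_mirror(self):
        m, _ = lollipop(trunk_w=31)
        m[:, :150] |= solid_disc((700, 400), (150, 120), 40)[:, :150]  # asymmetry
        seg = segment_silhouette(m)
        seg_m = segment_silhouette(m[:, ::-1])
        assert seg.crown_trunk_row == seg_m.crown_trunk_row
        assert seg.trunk_root_row == seg_m.trunk_root_row
        assert np.array_equal(seg.crown_mask[:, ::-1], seg_m.crown_mask)
        assert np.array_equal(seg.root_mask[:, ::-1], seg_m.root_mask)

    def test_translation_shifts_boundaries_only(self):
        m, _ = lollipop()
        pad_top, pad_left = 41, 17
        padded = np.pad(m, ((pad_top, 13), (pad_left, 29)))
        seg = segment_silhouette(m)
        seg_p = segment_silhouette(padded)
        assert seg_p.crown_trunk_row == seg.crown_trunk_row + pad_top
        assert seg_p.trunk_root_row == seg.trunk_root_row + pad_top
        assert seg_p.crown_mask.sum() == seg.crown_mask.sum()
        assert seg_p.trunk_mask.sum() == seg.trunk_mask.sum()

    def test_bigger_crown_never_measures_smaller(self):
        counts = []
        for radius in (50, 70, 90):
            m, _ = lollipop(radius=radius, trunk_bottom=600)
            counts.append(segment_silhouette(m).crown_mask.sum())
        assert counts == sorted(counts)


class TestScaleConsistency:
    def test_150_vs_300_dpi_agree_after_rescaling(self):
        from conftest import standard_spec
        from baumtest.synthetic import render

        res = {}
        for dpi in (150, 300):
            image, _, _ = render(standard_spec(dpi=float(dpi), seed=5))
            res[dpi] = measure_image(image)
        lo, hi = res[150], res[300]
        # boundary rows agree within 2 rows after mapping 300 dpi -> 150 dpi
        assert abs(hi.segmentation.crown_trunk_row / 2 - lo.segmentation.crown_trunk_row) <= 2
        assert abs(hi.segmentation.trunk_root_row / 2 - lo.segmentation.trunk_root_row) <= 2
        for name in ("crown_area_cm2", "trunk_area_cm2", "total_area_cm2"):
            a = getattr(lo.metrics, name)
            b = getattr(hi.metrics, name)
            assert a == pytest.approx(b, rel=0.03)
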