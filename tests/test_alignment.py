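import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import blotkin as bk
from blotkin import AlignmentError, detect_contour_centers, initial_guesses, \
    select_anchors, warp_and_trim
from blotkin.alignment import ContourCenter, align_stack

from conftest import aligned_reference_centroid_errors, gaussian_spot


def centers_xy(centers):
    return np.array([[c.x, c.y] for c in centers])


class TestDetectContourCenters:
    def test_single_gaussian_center_matches_pixel_oracle(self):
        frame = gaussian_spot((60, 80), (30.0, 45.0), sigma=5.0, amplitude=1.0)
        centers = detect_contour_centers(frame)
        assert len(centers) == 1
        # oracle: centroid of pixels above the contour level
        yy, xx = np.nonzero(frame > 0.6)
        assert abs(centers[0].y - yy.mean()) < 0.5
        assert abs(centers[0].x - xx.mean()) < 0.5

    def test_four_corner_spots(self):
        frame = np.zeros((80, 80))
        spots = [(12, 12), (12, 68), (68, 12), (68, 68)]
        for c in spots:
            frame += gaussian_spot(frame.shape, c, 4.0, 1.0)
        centers = detect_contour_centers(frame)
        assert len(centers) == 4
        found = {tuple(np.round([c.y, c.x]).astype(int)) for c in centers}
        assert found == set(spots)

    def test_border_touching_spot_is_closed(self):
        frame = gaussian_spot((40, 40), (0.0, 20.0), 5.0, 1.0)
        centers = detect_contour_centers(frame)
        assert len(centers) == 1
        assert abs(centers[0].x - 20.0) < 0.5

    def test_constant_frame_rejected(self):
        with pytest.raises(AlignmentError, match="constant"):
            detect_contour_centers(np.full((10, 10), 0.3))

    def test_sorted_by_descending_area(self):
        frame = gaussian_spot((80, 80), (20, 20), 3.0, 1.0) \
            + gaussian_spot((80, 80), (60, 60), 7.0, 1.0)
        centers = detect_contour_centers(frame)
        areas = [c.contour_area for c in centers]
        assert areas == sorted(areas, reverse=True)


class TestInitialGuesses:
    @pytest.mark.parametrize("pts,expected", [
        ([(10, 10), (10, 90), (90, 10), (50, 50)],
         [(10, 10), (10, 90), (90, 10)]),
        ([(20, 5), (20, 95), (80, 5)],
         [(20, 5), (20, 95), (80, 5)]),
    ])
    def test_forced_by_min_max(self, pts, expected):
        centers = [ContourCenter(x=x, y=y, contour_area=1.0) for x, y in pts]
        np.testing.assert_array_equal(initial_guesses(centers), expected)

    def test_fewer_than_three_centers(self):
        with pytest.raises(AlignmentError, match="3"):
            initial_guesses([ContourCenter(1.0, 1.0, 1.0)])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)),
                    min_size=3, max_size=12, unique=True),
           st.randoms(use_true_random=False))
    def test_permutation_invariant(self, pts, rnd):
        centers = [ContourCenter(x=x, y=y, contour_area=1.0) for x, y in pts]
        shuffled = list(centers)
        rnd.shuffle(shuffled)
        np.testing.assert_array_equal(initial_guesses(centers),
                                      initial_guesses(shuffled))


def _centers_at(points):
    return [ContourCenter(x=float(x), y=float(y), contour_area=10.0)
            for x, y in points]


class TestSelectAnchors:
    shape = (240, 300)

    def test_matching_geometry_passes(self, generic_layout):
        pts = bk.canonical_anchor_positions(generic_layout)[:, ::-1]  # xy
        centers = _centers_at(pts) + _centers_at([(150, 120)])
        anchors = select_anchors(centers, initial_guesses(centers),
                                 generic_layout, self.shape)
        assert anchors.passed
        assert {c.name for c in anchors.checks.values()} == {
            "side_ratio_1", "side_ratio_2", "angle", "guess_distance"}

    def test_near_collinear_anchors_fail_angle(self, generic_layout):
        pts = [(15, 15), (15, 285), (40, 150)]
        centers = _centers_at(pts)
        with pytest.raises(AlignmentError, match="angle"):
            select_anchors(centers, np.array(pts, float),
                           generic_layout, self.shape)

    def test_wrong_side_ratio_fails(self):
        lay = bk.ArrayLayout(
            name="sq", n_rows=8, n_cols=8, spot_box=30,
            reference_spots=((0, 0), (7, 0), (0, 7)),
            expected_side_ratios=(1 / np.sqrt(2), 1 / np.sqrt(2)))
        # legs with ratio 1.5 instead of the expected 1.0
        centers = _centers_at([(15, 15), (15, 15 + 210), (15 + 140, 15)])
        with pytest.raises(AlignmentError, match="side_ratio"):
            select_anchors(centers, initial_guesses(centers), lay,
                           (240, 240))

    def test_far_guess_fails_distance_check(self, generic_layout):
        # anchors form the right geometry, but one initial guess sits far
        # from the anchor it selects
        pts = bk.canonical_anchor_positions(generic_layout)[:, ::-1]
        centers = _centers_at(pts)
        guesses = pts.astype(float).copy()
        guesses[2] += (40.0, 40.0)   # 57 px away, > 10% of the diagonal
        anchors = select_anchors(centers, guesses, generic_layout,
                                 self.shape, strict=False)
        assert not anchors.checks["guess_distance"].passed
        assert anchors.checks["angle"].passed

    def test_ambiguous_selection_rejected(self, generic_layout):
        centers = _centers_at([(15, 15), (16, 16), (150, 150)])
        with pytest.raises(AlignmentError, match="ambiguous"):
            select_anchors(centers, initial_guesses(centers),
                           generic_layout, self.shape)


class TestWarpAndTrim:
    def test_identity_when_anchors_canonical(self, small_layout):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 1, small_layout.grid_shape)
        pts = bk.canonical_anchor_positions(small_layout)[:, ::-1]
        anchors = bk.AnchorSet(guesses=pts, anchors=_centers_at(pts))
        out = warp_and_trim(frame, anchors, small_layout)
        assert np.abs(out - frame).max() < 1e-9

    def test_collinear_anchor_triple_rejected(self, small_layout):
        pts = [(10, 10), (20, 20), (30, 30)]
        anchors = bk.AnchorSet(guesses=np.array(pts, float),
                               anchors=_centers_at(pts))
        with pytest.raises(AlignmentError, match="degenerate"):
            warp_and_trim(np.zeros(small_layout.grid_shape), anchors,
                          small_layout)


class TestAlignStack:
    def test_already_aligned_stack_unchanged(self, generic_layout, constants):
        truth = bk.default_truth(generic_layout, seed=0, rotation_deg=0.0,
                                 translation_px=(0.0, 0.0), margin_px=0,
                                 sigma_intercept=0.0, sigma_slope=0.0)
        stack, _ = bk.generate_stack(generic_layout, truth)
        aligned = align_stack(stack, generic_layout)
        assert np.abs(aligned.frames - stack.frames).max() < 1e-6
        np.testing.assert_array_equal(aligned.exposure_times,
                                      stack.exposure_times)

    @pytest.mark.parametrize("rot,trans", [(3.0, (4.0, 7.0)),
                                           (-5.0, (10.0, -10.0))])
    def test_rotation_recovered_within_one_pixel(self, generic_layout, rot,
                                                 trans):
        truth = bk.default_truth(generic_layout, seed=1, rotation_deg=rot,
                                 translation_px=trans,
                                 sigma_intercept=0.002, sigma_slope=0.0)
        stack, _ = bk.generate_stack(generic_layout, truth)
        aligned = align_stack(stack, generic_layout)
        errs = aligned_reference_centroid_errors(aligned, generic_layout)
        assert np.nanmax(errs) < 1.0

    def test_all_dark_stack_rejected(self, generic_layout):
        stack = bk.from_frames(np.zeros((3, 480, 540)), times=[1, 2, 3])
        with pytest.raises(AlignmentError):
            align_stack(stack, generic_layout)

    def test_rotation_hint_applied(self, generic_layout, small_layout):
        from dataclasses import replace
        truth = bk.default_truth(generic_layout, seed=0,
                                 sigma_intercept=0.002, sigma_slope=0.0)
        stack, _ = bk.generate_stack(generic_layout, truth)
        rotated = stack.with_frames(
            np.stack([np.rot90(f, k=1) for f in stack.frames]))
        lay = replace(generic_layout, rotation_hint=90)
        aligned = align_stack(rotated, lay)
        direct = align_stack(stack, generic_layout)
        assert np.abs(aligned.frames - direct.frames).max() < 0.05
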