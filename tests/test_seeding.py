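import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from texsurf.seeding import (
    ProbabilityMap,
    SeedContour,
    SeedingParams,
    SliceRangeSpec,
    assign_contours_to_slices,
    build_seed_mask,
    disc_mask,
    inclusion_probability,
    select_start_regions,
    texture_probability,
)
from texsurf.texture import FeatureStack, GaborConfig, gabor_stack
from texsurf.volume_io import Volume


def gauss_peak(sigma):
    return 1.0 / math.sqrt(2.0 * math.pi * sigma * sigma)


def pin_oracle(map_2d, contour, sigma):
    """Double-loop evaluation of the inclusion probability."""
    values = map_2d[disc_mask(map_2d.shape, contour)]
    out = np.zeros_like(map_2d, dtype=float)
    for (y, x), v in np.ndenumerate(map_2d):
        acc = 0.0
        for c in values:
            acc += gauss_peak(sigma) * math.exp(-((v - c) ** 2) / (2 * sigma**2))
        out[y, x] = acc / len(values)
    return out


class TestInclusionProbability:
    def test_constant_map_gives_peak_everywhere(self):
        contour = SeedContour(0, (8.0, 8.0), 3.0)
        p = inclusion_probability(np.full((16, 16), 4.2), contour,
                                  SeedingParams(sigma_mode="fixed", sigma_value=2.0))
        np.testing.assert_allclose(p.values, gauss_peak(2.0))

    def test_one_sigma_offset_closed_form(self):
        """A pixel exactly one sigma away from a constant contour value
        gets the peak density times exp(-1/2)."""
        sigma = 3.0
        m = np.full((16, 16), 10.0)
        m[0, 0] = 10.0 + sigma
        contour = SeedContour(0, (8.0, 8.0), 3.0)
        p = inclusion_probability(m, contour, SeedingParams("fixed", sigma))
        assert p.values[0, 0] == pytest.approx(gauss_peak(sigma) * math.exp(-0.5))
        assert p.values[8, 8] == pytest.approx(gauss_peak(sigma))

    def test_matches_double_loop_oracle(self, rng):
        m = rng.normal(size=(16, 16))
        contour = SeedContour(0, (8.0, 8.0), 1.6)  # 9-pixel disc
        assert disc_mask(m.shape, contour).sum() == 9
        sigma = 0.7
        p = inclusion_probability(m, contour, SeedingParams("fixed", sigma))
        np.testing.assert_allclose(p.values, pin_oracle(m, contour, sigma), atol=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(-50.0, 50.0),
    )
    def test_bounds_and_shift_invariance(self, seed, offset):
        """P_in lies in (0, N(0)] and depends only on value differences."""
        r = np.random.default_rng(seed)
        m = r.normal(size=(12, 12)) * 3.0
        contour = SeedContour(0, (6.0, 6.0), 2.0)
        params = SeedingParams(sigma_mode="contour_std")
        p1 = inclusion_probability(m, contour, params)
        values = m[disc_mask(m.shape, contour)]
        sigma = max(values.std(), params.sigma_floor_fraction * (m.max() - m.min()))
        assert (p1.values > 0).all()
        assert (p1.values <= gauss_peak(sigma) * (1 + 1e-12)).all()
        p2 = inclusion_probability(m + offset, contour, params)
        np.testing.assert_allclose(p1.values, p2.values, rtol=1e-9, atol=1e-12)

    def test_fast_path_matches_exact_path(self, rng, monkeypatch):
        """The grid-interpolated KDE used on large slices agrees with the
        direct evaluation to well below 1e-5 of the peak."""
        import texsurf.seeding as seeding_mod

        m = rng.normal(size=(32, 32)) * 10.0
        contour = SeedContour(0, (16.0, 16.0), 5.0)
        params = SeedingParams("fixed", 2.5)
        exact = inclusion_probability(m, contour, params).values
        monkeypatch.setattr(seeding_mod, "FAST_KDE_PAIR_THRESHOLD", 0)
        fast = inclusion_probability(m, contour, params).values
        np.testing.assert_allclose(fast, exact, atol=1e-5 * gauss_peak(2.5))


class TestTextureProbability:
    def test_single_map_equals_inclusion(self, rng):
        m = rng.normal(size=(16, 16))
        contour = SeedContour(0, (8.0, 8.0), 2.0)
        params = SeedingParams("fixed", 1.0)
        stack = FeatureStack({"only": m})
        np.testing.assert_allclose(
            texture_probability(stack, contour, params).values,
            inclusion_probability(m, contour, params).values,
        )

    def test_linearity_of_sum(self, rng):
        m = rng.normal(size=(16, 16))
        contour = SeedContour(0, (8.0, 8.0), 2.0)
        params = SeedingParams("fixed", 1.0)
        single = texture_probability(FeatureStack({"a": m}), contour, params)
        double = texture_probability(
            FeatureStack({"a": m, "b": m.copy()}), contour, params
        )
        np.testing.assert_allclose(double.values, 2.0 * single.values)

    def test_phantom_ordering(self, big_slice_phantom):
        """On a two-texture phantom slice, P_tex is higher inside the
        seeded texture than in the other texture on average."""
        volume, gt, contour = big_slice_phantom
        z = contour.slice_index
        stack = gabor_stack(volume.data[z], GaborConfig())
        p = texture_probability(stack, contour).values
        target = gt.as_bool()[z]
        assert p[target].mean() > p[~target].mean()


class TestAssignContours:
    def test_mode_a_inclusive_interval(self):
        contours = [SeedContour(60, (10.0, 10.0), 5.0)]
        out = assign_contours_to_slices(
            contours, SliceRangeSpec("A", n_s=60, r=40, spacing_m=1), 150
        )
        indices = [z for z, _ in out]
        assert indices[0] == 20 and indices[-1] == 100
        assert indices == list(range(20, 101))

    def test_mode_b_single_slice(self):
        c = SeedContour(0, (5.0, 5.0), 2.0)
        out = assign_contours_to_slices([c], SliceRangeSpec("B", 0, 0), 10)
        assert out == [(0, c)]

    def test_nearest_contour_with_tie_break(self):
        c10 = SeedContour(10, (5.0, 5.0), 2.0)
        c30 = SeedContour(30, (6.0, 6.0), 2.0)
        out = dict(
            assign_contours_to_slices(
                [c10, c30], SliceRangeSpec("A", n_s=20, r=10), 64
            )
        )
        for z in range(10, 20):
            assert out[z] is c10
        for z in range(21, 31):
            assert out[z] is c30
        assert out[20] is c10  # equidistant -> lower slice index wins

    def test_out_of_bounds_indices_dropped(self):
        c = SeedContour(2, (5.0, 5.0), 2.0)
        out = assign_contours_to_slices([c], SliceRangeSpec("A", 2, 5), 6)
        assert [z for z, _ in out] == [0, 1, 2, 3, 4, 5]

    def test_mode_b_propagation(self):
        c = SeedContour(0, (5.0, 5.0), 2.0)
        out = assign_contours_to_slices(
            [c], SliceRangeSpec("B", 0, 9, spacing_m=1, propagate_every=3), 20
        )
        # virtual anchors at 0,3,6,9: slice 4 pairs with the copy at 3
        by_slice = {z: k.slice_index for z, k in out}
        assert by_slice[4] == 3 and by_slice[8] == 9 and by_slice[1] == 0

    def test_empty_range_errors(self):
        c = SeedContour(0, (5.0, 5.0), 2.0)
        with pytest.raises(ValueError, match="empty slice range"):
            assign_contours_to_slices([c], SliceRangeSpec("B", 50, 5), 10)


class TestSelectStartRegions:
    def test_constant_probability_marks_everything(self):
        contour = SeedContour(0, (8.0, 8.0), 3.0)
        prob = ProbabilityMap(np.full((16, 16), 0.5), contour)
        sel = select_start_regions(prob, contour, SeedingParams(window_size=8))
        assert sel.all()

    def test_offset_tile_unmarked(self, rng):
        base = np.abs(rng.normal(1.0, 0.05, size=(16, 16)))
        contour = SeedContour(0, (11.0, 4.0), 3.0)  # fully inside one tile
        region = base[disc_mask(base.shape, contour)]
        base[0:8, 8:16] += 10.0 * region.std()
        sel = select_start_regions(
            ProbabilityMap(base, contour), contour, SeedingParams(window_size=8)
        )
        assert not sel[0:8, 8:16].any()
        assert sel[8:16, 0:8].all()

    def test_window_larger_than_slice_errors(self):
        contour = SeedContour(0, (8.0, 8.0), 3.0)
        prob = ProbabilityMap(np.ones((16, 16)), contour)
        with pytest.raises(ValueError):
            select_start_regions(prob, contour, SeedingParams(window_size=32))

    def test_phantom_slice_quality(self, big_slice_phantom):
        """On a large single-region slice the marked windows overlap the
        seeded texture well and barely touch the other texture."""
        volume, gt, contour = big_slice_phantom
        stack = gabor_stack(volume.data[8], GaborConfig())
        sel = select_start_regions(texture_probability(stack, contour), contour)
        target = gt.as_bool()[8]
        inter = (sel & target).sum()
        dice = 2 * inter / (sel.sum() + target.sum())
        assert dice > 0.5
        assert (sel & ~target).sum() < 0.1 * sel.sum()


class TestBuildSeedMask:
    @pytest.fixture(scope="class")
    def tiny_textured_volume(self):
        from texsurf.phantom import PhantomSpec, generate_phantom

        spec = PhantomSpec(shape=(16, 64, 64), n_targets=1)
        volume, gt, seeds = generate_phantom(spec)
        return volume, seeds

    def test_single_processed_slice(self, tiny_textured_volume):
        volume, seeds = tiny_textured_volume
        c = [s for s in seeds if s.slice_index == 8][0]
        mask = build_seed_mask(
            volume, [c], SliceRangeSpec("B", 8, 0, spacing_m=16)
        )
        occupied = np.flatnonzero(mask.data.sum(axis=(1, 2)))
        np.testing.assert_array_equal(occupied, [8])

    def test_compositional_oracle(self, tiny_textured_volume):
        """Each processed slice equals the explicit composition of the
        Gabor stack, P_tex and window selection, plus the seed disc."""
        volume, seeds = tiny_textured_volume
        spec = SliceRangeSpec("A", 8, 4, spacing_m=2)
        mask = build_seed_mask(volume, seeds, spec)
        params = SeedingParams()
        cfg = GaborConfig()
        for z, contour in assign_contours_to_slices(seeds, spec, 16):
            stack = gabor_stack(np.asarray(volume.data, float)[z], cfg)
            expect = select_start_regions(
                texture_probability(stack, contour, params), contour, params
            )
            for s in seeds:
                if s.slice_index == z:
                    expect = expect | disc_mask(volume.data[z].shape, s)
            np.testing.assert_array_equal(mask.as_bool()[z], expect)

    def test_larger_spacing_is_slice_subset(self, tiny_textured_volume):
        volume, seeds = tiny_textured_volume
        m2 = build_seed_mask(volume, seeds, SliceRangeSpec("A", 8, 4, spacing_m=2))
        m4 = build_seed_mask(volume, seeds, SliceRangeSpec("A", 8, 4, spacing_m=4))
        shared = [4, 6, 8, 10, 12]
        for z in (4, 8, 12):  # slices processed by both spacings
            np.testing.assert_array_equal(m2.as_bool()[z], m4.as_bool()[z])
        assert m4.voxel_count() <= m2.voxel_count()

    def test_deterministic(self, tiny_textured_volume):
        volume, seeds = tiny_textured_volume
        spec = SliceRangeSpec("A", 8, 4, spacing_m=2)
        a = build_seed_mask(volume, seeds, spec)
        b = build_seed_mask(volume, seeds, spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_roi_restricts_selection(self, tiny_textured_volume):
        volume, seeds = tiny_textured_volume
        c = [s for s in seeds if s.slice_index == 8][0]
        spec = SliceRangeSpec("B", 8, 0)
        full = build_seed_mask(volume, [c], spec)
        roi = build_seed_mask(volume, [c], spec, roi=(16, 48, 16, 48))
        outside = roi.as_bool().copy()
        outside[:, 16:48, 16:48] = False
        # outside the ROI only the forced seed disc may remain
        assert outside.sum() <= disc_mask((64, 64), c).sum()
        assert roi.voxel_count() <= full.voxel_count()


def test_disc_inside_slice_required():
    with pytest.raises(ValueError, match="inside the slice"):
        disc_mask((16, 16), SeedContour(0, (2.0, 2.0), 5.0))
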