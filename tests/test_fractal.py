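import numpy as np
import pytest

from oviscan import fractal, phantom
from oviscan.imgio import BinaryMask

from oracles import naive_box_count, naive_box_masses, window_of


class TestBoxCounts:
    def test_filled_square_counts_are_exact_powers(self):
        mask, _ = phantom.make_fractal_raster("filled_square", size_px=256)
        curve = fractal.box_counts(mask, scales_px=[2, 4, 8, 16], n_offsets=1)
        assert list(curve.counts[:, 0]) == [16384, 4096, 1024, 256]

    def test_single_pixel_counts_one_box_at_every_scale_and_offset(self):
        grid = np.zeros((64, 64), bool)
        grid[10, 50] = True
        curve = fractal.box_counts(BinaryMask(grid), scales_px=[2, 4, 8], n_offsets=4, seed=1)
        assert (curve.counts == 1).all()

    def test_counts_match_naive_per_box_scan(self):
        rng = np.random.default_rng(42)
        for seed in range(5):
            grid = np.random.default_rng(seed).random((64, 64)) < rng.uniform(0.05, 0.6)
            if not grid.any():
                continue
            mask = BinaryMask(grid)
            curve = fractal.box_counts(mask, scales_px=[2, 4, 8, 16], n_offsets=3, seed=seed)
            win = window_of(grid)
            for i, eps in enumerate(curve.scales_px):
                for j, (dy, dx) in enumerate(curve.offsets[i]):
                    assert curve.counts[i, j] == naive_box_count(win, eps, int(dy), int(dx))
                    assert sorted(curve.masses[i][j]) == sorted(
                        naive_box_masses(win, eps, int(dy), int(dx))
                    )

    def test_mean_counts_non_increasing_in_scale(self):
        grid = np.random.default_rng(3).random((128, 128)) < 0.2
        curve = fractal.box_counts(BinaryMask(grid), seed=0)
        assert (np.diff(curve.mean_counts()) <= 0).all()

    def test_first_offset_is_always_the_origin(self):
        mask, _ = phantom.make_fractal_raster("random_dust", 0.2, 64, seed=0)
        curve = fractal.box_counts(mask, scales_px=[4, 8], n_offsets=4, seed=5)
        for offs in curve.offsets:
            assert tuple(offs[0]) == (0, 0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fractal.box_counts(BinaryMask(np.zeros((32, 32), bool)))


class TestFractalDimension:
    def test_filled_square_measures_exactly_two(self):
        mask, _ = phantom.make_fractal_raster("filled_square", size_px=256)
        result = fractal.analyze_mask(mask)
        assert result.fd == pytest.approx(2.0, abs=1e-9)
        assert result.fit_r2 == pytest.approx(1.0)

    def test_single_pixel_measures_zero(self):
        grid = np.zeros((64, 64), bool)
        grid[5, 5] = True
        curve = fractal.box_counts(BinaryMask(grid), scales_px=[2, 4, 8], n_offsets=2, seed=0)
        fd, r2 = fractal.fractal_dimension(curve)
        assert fd == 0.0 and r2 == 1.0

    def test_line_measures_one(self):
        mask, _ = phantom.make_fractal_raster("line", size_px=256)
        assert fractal.analyze_mask(mask).fd == pytest.approx(1.0, abs=0.05)

    def test_sierpinski_measures_its_similarity_dimension(self):
        mask, truth = phantom.make_fractal_raster("sierpinski_triangle", 7, 1024)
        assert fractal.analyze_mask(mask).fd == pytest.approx(truth.analytic_fd, abs=0.05)

    def test_koch_measures_its_similarity_dimension(self):
        mask, truth = phantom.make_fractal_raster("koch_curve", 6, 2187)
        curve = fractal.box_counts(mask, scales_px=[2, 4, 8, 16, 32, 64], n_offsets=8, seed=0)
        fd, _ = fractal.fractal_dimension(curve)
        assert fd == pytest.approx(truth.analytic_fd, abs=0.05)

    def test_single_scale_rejected(self):
        mask, _ = phantom.make_fractal_raster("filled_square", size_px=64)
        curve = fractal.box_counts(mask, scales_px=[4], n_offsets=1)
        with pytest.raises(ValueError, match="variance"):
            fractal.fractal_dimension(curve)


class TestLacunarity:
    def test_filled_window_has_zero_lacunarity_exactly(self):
        mask, _ = phantom.make_fractal_raster("filled_square", size_px=256)
        result = fractal.analyze_mask(mask)
        assert result.lacunarity_mean == 0.0
        assert (result.lacunarity_per_scale == 0.0).all()

    def test_two_occupied_of_four_cells_closed_form(self):
        # two diagonal pixels at ε=1: masses {1,0,0,1} → (σ/μ)² = 1 exactly
        grid = np.zeros((8, 8), bool)
        grid[2, 2] = grid[3, 3] = True
        curve = fractal.box_counts(BinaryMask(grid), scales_px=[1], n_offsets=1)
        per_scale, mean = fractal.lacunarity(curve)
        assert per_scale[0] == 1.0 and mean == 1.0

    def test_plus_one_convention_shifts_by_one(self):
        mask, _ = phantom.make_fractal_raster("random_dust", 0.3, 64, seed=1)
        curve = fractal.box_counts(mask, scales_px=[2, 4, 8], n_offsets=2, seed=0)
        bare, bare_mean = fractal.lacunarity(curve)
        plus, plus_mean = fractal.lacunarity(curve, plus_one=True)
        assert plus == pytest.approx(bare + 1.0)
        assert plus_mean == pytest.approx(bare_mean + 1.0)

    def test_sparser_dust_is_more_lacunar(self):
        wins = 0
        for seed in range(10):
            sparse, _ = phantom.make_fractal_raster("random_dust", 0.05, 256, seed=seed)
            dense, _ = phantom.make_fractal_raster("random_dust", 0.5, 256, seed=seed)
            a = fractal.analyze_mask(sparse, seed=seed).lacunarity_mean
            b = fractal.analyze_mask(dense, seed=seed).lacunarity_mean
            wins += a > b
        assert wins >= 9

    def test_dilation_sequence_toward_filled_window_decreases_lacunarity(self):
        from scipy import ndimage as ndi

        grid = np.random.default_rng(0).random((64, 64)) < 0.05
        grid[0, 0] = grid[0, -1] = grid[-1, 0] = grid[-1, -1] = True  # pin the window
        values = []
        for _ in range(5):
            values.append(fractal.analyze_mask(BinaryMask(grid), seed=1).lacunarity_mean)
            grid = ndi.binary_dilation(grid, np.ones((3, 3), bool))
        assert all(b < a for a, b in zip(values, values[1:]))
        assert all(v >= 0 for v in values)


class TestInvariances:
    @pytest.mark.parametrize("transform", [np.rot90, np.fliplr])
    def test_fd_and_lacunarity_stable_under_isometries(self, transform):
        mask, _ = phantom.make_fractal_raster("random_dust", 0.2, 128, seed=7)
        a = fractal.analyze_mask(mask, seed=3)
        b = fractal.analyze_mask(BinaryMask(transform(mask.grid).copy()), seed=3)
        assert b.fd == pytest.approx(a.fd, abs=0.05)
        assert b.lacunarity_mean == pytest.approx(a.lacunarity_mean, rel=0.1)

    def test_origin_offset_reproduces_untranslated_grid(self):
        mask, _ = phantom.make_fractal_raster("sierpinski_triangle", 6, 64)
        one = fractal.box_counts(mask, scales_px=[2, 4, 8, 16], n_offsets=1)
        many = fractal.box_counts(mask, scales_px=[2, 4, 8, 16], n_offsets=5, seed=9)
        assert (one.counts[:, 0] == many.counts[:, 0]).all()
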