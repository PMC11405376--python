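import math

import numpy as np
import pytest

from oviscan import phantom, shape3d
from oviscan.phantom import FoldPhantomSpec, TubePhantomSpec


class TestFoldPhantom:
    def test_no_folds_gives_plain_annulus_and_disc_lumen(self):
        spec = FoldPhantomSpec(n_folds=0, lumen_radius_px=100.0, wall_thickness_px=40.0,
                               image_size_px=(320, 320))
        tissue, lumen, truth = phantom.make_fold_cross_section(spec)
        assert truth.true_fold_lengths_um == []
        # the lumen is a filled disc of the lumen radius
        area = lumen.count()
        assert area == pytest.approx(math.pi * 100.0**2, rel=0.02)
        # tissue is an annulus: no lumen pixel is tissue
        assert not (tissue.grid & lumen.grid).any()

    def test_constructed_truth_scales_with_pixel_size(self, simple_fold_phantom):
        spec, tissue, lumen, truth = simple_fold_phantom
        assert truth.true_fold_lengths_um == [pytest.approx(370.0)] * 4
        assert truth.true_fold_widths_um == [pytest.approx(88.8)] * 4

    def test_sampled_fold_sizes_stay_in_the_requested_range(self):
        # emulates printed per-region ranges: lengths drawn in [17, 134] px
        spec = FoldPhantomSpec(
            n_folds=8,
            fold_length_px=(17.0, 134.0),
            fold_width_px=(8.0, 20.0),
            lumen_radius_px=230.0,
            image_size_px=(672, 672),
            px_size_um=7.4,
            seed=1,
        )
        _, _, truth = phantom.make_fold_cross_section(spec)
        assert len(truth.true_fold_lengths_um) == 8
        for L in truth.true_fold_lengths_um:
            assert 17 * 7.4 - 1e-9 <= L <= 134 * 7.4 + 1e-9
        for W in truth.true_fold_widths_um:
            assert 8 * 7.4 - 1e-9 <= W <= 20 * 7.4 + 1e-9

    def test_same_seed_is_bit_identical(self):
        a = phantom.make_fold_cross_section(FoldPhantomSpec(seed=3))
        b = phantom.make_fold_cross_section(FoldPhantomSpec(seed=3))
        assert np.array_equal(a[0].grid, b[0].grid)
        assert np.array_equal(a[1].grid, b[1].grid)
        assert a[2].true_fold_lengths_um == b[2].true_fold_lengths_um

    def test_merging_folds_are_rejected(self):
        spec = FoldPhantomSpec(
            n_folds=12, fold_length_px=150.0, fold_width_px=30.0, lumen_radius_px=170.0
        )
        with pytest.raises(ValueError, match="merge"):
            phantom.make_fold_cross_section(spec)

    def test_folds_may_not_cross_the_lumen(self):
        with pytest.raises(ValueError, match="lumen"):
            FoldPhantomSpec(n_folds=2, fold_length_px=200.0, lumen_radius_px=150.0)

    def test_crypts_stay_blind_and_open_into_the_lumen(self):
        spec = FoldPhantomSpec(n_folds=0, n_crypts=4, crypt_depth_px=30.0, seed=5)
        tissue, lumen, _ = phantom.make_fold_cross_section(spec)
        plain, _, _ = phantom.make_fold_cross_section(
            FoldPhantomSpec(n_folds=0, n_crypts=0, seed=5)
        )
        # crypts only remove wall material, and the wall stays connected
        assert tissue.count() < plain.count()
        from scipy import ndimage as ndi

        _, n = ndi.label(tissue.grid, structure=np.ones((3, 3), bool))
        assert n == 1


class TestFractalRaster:
    @pytest.mark.parametrize(
        "kind,order_or_p,expected_fd",
        [
            ("filled_square", 0, 2.0),
            ("line", 0, 1.0),
            ("koch_curve", 4, math.log(4) / math.log(3)),
            ("sierpinski_triangle", 7, math.log(3) / math.log(2)),
        ],
    )
    def test_analytic_dimension_is_recorded(self, kind, order_or_p, expected_fd):
        size = 1024 if kind == "sierpinski_triangle" else 256
        mask, truth = phantom.make_fractal_raster(kind, order_or_p, size_px=size)
        assert truth.analytic_fd == pytest.approx(expected_fd)
        assert mask.grid.any()

    def test_filled_square_sets_every_pixel(self):
        mask, truth = phantom.make_fractal_raster("filled_square", size_px=64)
        assert mask.grid.all()

    def test_line_is_one_pixel_wide(self):
        mask, _ = phantom.make_fractal_raster("line", size_px=64)
        assert mask.count() == 64
        assert mask.grid.any(axis=1).sum() == 1

    def test_random_dust_records_no_analytic_dimension(self):
        mask, truth = phantom.make_fractal_raster("random_dust", 0.3, size_px=64, seed=2)
        assert truth.analytic_fd is None
        assert 0 < mask.count() < 64 * 64

    def test_unresolvable_order_is_rejected(self):
        with pytest.raises(ValueError, match="resolve"):
            phantom.make_fractal_raster("sierpinski_triangle", 9, size_px=256)
        with pytest.raises(ValueError, match="resolve"):
            phantom.make_fractal_raster("koch_curve", 6, size_px=256)


class TestTubePhantom:
    def test_cylinder_truth_matches_closed_form(self):
        spec = TubePhantomSpec(kind="straight_cylinder", outer_radius_mm=1.0, height_mm=4.46)
        _, truth = phantom.make_tube_volume(spec)
        assert truth.analytic_volume_mm3 == pytest.approx(math.pi * 4.46)
        assert truth.analytic_surface_mm2 == pytest.approx(2 * math.pi * 4.46 + 2 * math.pi)
        assert truth.height_mm == 4.46

    def test_voxel_volume_converges_with_refinement(self):
        errs = []
        for v in (0.125, 0.05):
            spec = TubePhantomSpec(kind="straight_cylinder", voxel_mm=v, height_mm=2.0)
            mask, truth = phantom.make_tube_volume(spec)
            vol = mask.count() * v**3
            errs.append(abs(vol - truth.analytic_volume_mm3) / truth.analytic_volume_mm3)
        assert errs[1] < errs[0]
        assert errs[1] < 0.02

    def test_helical_volume_matches_centerline_oracle(self):
        r_t, pitch, R, h = 0.3, 1.5, 0.8, 3.0
        spec = TubePhantomSpec(
            kind="helical_tube", outer_radius_mm=r_t, inner_radius_mm=0.2,
            height_mm=h, voxel_mm=0.05, helix_pitch_mm=pitch, helix_radius_mm=R,
        )
        mask, _ = phantom.make_tube_volume(spec)
        vol = mask.count() * 0.05**3
        # oracle: numeric arc length of the centre line × tube section
        z = np.linspace(0, h, 20001)
        phi = 2 * math.pi * z / pitch
        pts = np.column_stack([R * np.cos(phi), R * np.sin(phi), z])
        arc = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        assert vol == pytest.approx(math.pi * r_t**2 * arc, rel=0.05)

    def test_folded_tube_without_folds_is_the_plain_annular_tube(self):
        a, _ = phantom.make_tube_volume(TubePhantomSpec(kind="folded_tube", n_folds=0, voxel_mm=0.1))
        b, truth = phantom.make_tube_volume(TubePhantomSpec(kind="folded_tube", n_folds=0, voxel_mm=0.1, seed=9))
        assert np.array_equal(a.grid, b.grid)  # seed has no effect at 0 folds
        assert shape3d.measure_volume(a) == pytest.approx(truth.analytic_volume_mm3, rel=0.03)

    def test_voxel_budget_cap(self):
        spec = TubePhantomSpec(kind="straight_cylinder", voxel_mm=0.13, inner_radius_mm=0.52,
                               voxel_cap=100)
        with pytest.raises(ValueError, match="cap"):
            phantom.make_tube_volume(spec)

    def test_unresolvable_lumen_rejected(self):
        with pytest.raises(ValueError, match="resolvable"):
            TubePhantomSpec(inner_radius_mm=0.1, voxel_mm=0.05)
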