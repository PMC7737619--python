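"""Generators: determinism, symmetry properties, physical contracts."""

import numpy as np
import pytest
from scipy import ndimage

from zpfilament.helix import FilamentModel, HelicalSymmetry, PointSet
from zpfilament.synthetic import (
    PeakSimSpec,
    SheetSpec,
    default_filament_model,
    make_repeat_filament_image,
    make_sheet_image,
    project_model,
    project_segments,
    render_filament_volume,
    simulate_peaklist,
)
from zpfilament.xlms import composition_interval, MassComponent, Composition


def ncc(a, b):
    a = a - a.mean()
    b = b - b.mean()
    return float((a * b).sum() / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestRenderFilamentVolume:
    def test_single_point_gives_centered_blob(self):
        model = FilamentModel(
            asymmetric_unit=PointSet(coords=[[0.0, 0.0, 0.0]]),
            symmetry=HelicalSymmetry(62.5, 180),
        )
        vol = render_filament_volume(model, 5.0, 160.0, blob_sigma_angstrom=10)
        assert vol.min() >= 0
        peak = np.unravel_index(np.argmax(vol), vol.shape)
        center = (np.array(vol.shape) - 1) / 2
        assert np.allclose(peak, center, atol=1.0)

    def test_empty_unit_gives_zero_volume(self):
        model = FilamentModel(
            asymmetric_unit=PointSet(coords=np.empty((0, 3))),
            symmetry=HelicalSymmetry(62.5, 180),
        )
        vol = render_filament_volume(model, 5.0, 100.0)
        assert np.all(vol == 0)

    def test_half_turn_symmetry_of_rendered_volume(self, umod_model,
                                                   small_volume):
        """The twist-180 filament volume maps onto itself under
        (rotate 180° about z, shift one rise)."""
        rise_vox = umod_model.symmetry.rise_angstrom / 6.25
        rotated = np.rot90(small_volume, 2, axes=(1, 2))  # 180° about z
        shifted = ndimage.shift(rotated, (rise_vox, 0, 0), order=1)
        core = (slice(16, 48),) * 3
        assert ncc(shifted[core], small_volume[core]) > 0.98

    def test_too_small_box_rejected_when_clipping_disabled(self, umod_model):
        with pytest.raises(ValueError, match="box too small"):
            render_filament_volume(umod_model, 5.0, 100.0,
                                   clip_outside=False)

    def test_integrated_density_tracks_point_mass(self):
        unit = PointSet(coords=[[0.0, 0.0, 30.0]], masses=[2.0])
        model = FilamentModel(asymmetric_unit=unit,
                              symmetry=HelicalSymmetry(30.0, 180),
                              n_subunits=1)
        vol1 = render_filament_volume(model, 5.0, 300.0)
        unit2 = PointSet(coords=[[0.0, 0.0, 30.0]], masses=[4.0])
        model2 = FilamentModel(asymmetric_unit=unit2,
                               symmetry=HelicalSymmetry(30.0, 180),
                               n_subunits=1)
        vol2 = render_filament_volume(model2, 5.0, 300.0)
        assert vol2.sum() == pytest.approx(2 * vol1.sum(), rel=1e-6)


class TestProjectSegments:
    def test_deterministic_given_seed(self, small_volume):
        a = project_segments(small_volume, 6.25, 3, [0, 90, 180],
                             [0, 10, -10], 0.5, seed=7)
        b = project_segments(small_volume, 6.25, 3, [0, 90, 180],
                             [0, 10, -10], 0.5, seed=7)
        np.testing.assert_array_equal(a.images, b.images)

    def test_zero_noise_same_angle_identical(self, small_volume):
        st = project_segments(small_volume, 6.25, 2, [30.0, 30.0],
                              [0.0, 0.0], 0.0, seed=0)
        np.testing.assert_array_equal(st.images[0], st.images[1])

    def test_front_and_side_views_are_distinct_motifs(self, umod_model):
        """Tree-like front view vs zig-zag side view of the same
        branch-decorated filament correlate weakly."""
        front = project_model(umod_model, 0.0, (64, 64), 6.25)
        side = project_model(umod_model, 90.0, (64, 64), 6.25)
        assert ncc(front, side) < 0.9

    def test_volume_and_point_projections_agree(self, umod_model,
                                                small_volume):
        """The two projection paths implement the same view convention."""
        for ang in (25.0, 70.0, 130.0):
            vp = project_segments(small_volume, 6.25, 1, [ang], [0.0],
                                  0.0, 0).images[0]
            pp = project_model(umod_model, ang, vp.shape, 6.25)
            assert ncc(vp, pp) > 0.97

    def test_metadata_records_ground_truth(self, small_volume):
        st = project_segments(small_volume, 6.25, 2, [10.0, 20.0],
                              [5.0, -5.0], 0.0, 0)
        assert st.metadata[1] == {
            "view_angle_degrees": 20.0, "axial_offset_angstrom": -5.0,
        }


class TestMakeSheetImage:
    def test_p1_zero_distortion_is_exact_tiling(self):
        spec = SheetSpec(
            basis_a_angstrom=(60.0, 0.0), basis_b_angstrom=(0.0, 66.0),
            plane_group="p1", seed=3,
        )
        img = make_sheet_image(spec, 220)
        # integer-pixel basis: (20, 0) and (0, 22)
        np.testing.assert_allclose(img[:-22, :], img[22:, :], atol=1e-6)
        np.testing.assert_allclose(img[:, :-20], img[:, 20:], atol=1e-6)

    def test_p2_invariant_under_twofold_about_lattice_point(self):
        spec = SheetSpec(
            basis_a_angstrom=(60.0, 0.0), basis_b_angstrom=(0.0, 66.0),
            plane_group="p2", seed=3,
        )
        img = make_sheet_image(spec, 441)
        # (220, 220) = 11 a + 10 b is a lattice point (two-fold center)
        flipped = img[::-1, ::-1]  # maps (y, x) -> (440 - y, 440 - x)
        np.testing.assert_allclose(img, flipped, atol=1e-6)

    def test_reproducible_for_fixed_seed(self):
        spec = SheetSpec(distortion_amplitude_px=1.5, noise_sigma=0.3,
                         seed=9)
        np.testing.assert_array_equal(
            make_sheet_image(spec, 128), make_sheet_image(spec, 128)
        )

    def test_degenerate_basis_rejected(self):
        with pytest.raises(ValueError, match="independent"):
            SheetSpec(basis_a_angstrom=(60.0, 0.0),
                      basis_b_angstrom=(30.0, 0.0))


class TestMakeRepeatFilamentImage:
    def test_sub_nyquist_repeat_rejected(self):
        with pytest.raises(ValueError, match="2 pixels"):
            make_repeat_filament_image(8.0, 5.0)

    def test_seeded_noisy_image_reproducible(self):
        a = make_repeat_filament_image(65.0, 5.0, noise_sigma=0.5, seed=4)
        b = make_repeat_filament_image(65.0, 5.0, noise_sigma=0.5, seed=4)
        np.testing.assert_array_equal(a, b)


class TestSimulatePeaklist:
    def test_zero_jitter_point_masses_exact_sums(self):
        spec = PeakSimSpec(
            true_compositions=[{"a": 2, "b": 1}],
            component_windows={"a": (100.0, 100.0), "b": (250.0, 250.0)},
            adduct_da=10.0,
            seed=0,
        )
        peaks, _ = simulate_peaklist(spec)
        assert peaks.masses_da[0] == pytest.approx(
            2 * 100 + 250 + 2 * 10.0
        )

    def test_windowed_draws_land_inside_composition_interval(self):
        comps = [MassComponent("g", 36559.54, 39801.56, 4)]
        spec = PeakSimSpec(
            true_compositions=[{"g": k} for k in (1, 2, 3)],
            component_windows={"g": (36559.54, 39801.56)},
            seed=5,
        )
        peaks, truth = simulate_peaklist(spec)
        for mass, comp in zip(peaks.masses_da, truth):
            lo, hi = composition_interval(
                Composition.from_dict(comp), comps
            )
            assert lo <= mass <= hi

    def test_seeded_reproducibility(self):
        spec = PeakSimSpec(
            true_compositions=[{"g": 1}],
            component_windows={"g": (100.0, 200.0)},
            jitter_sd_da=5.0,
            seed=8,
        )
        a, _ = simulate_peaklist(spec)
        b, _ = simulate_peaklist(spec)
        assert a.masses_da == b.masses_da

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError):
            PeakSimSpec(
                true_compositions=[{"g": 0}],
                component_windows={"g": (100.0, 200.0)},
            )
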