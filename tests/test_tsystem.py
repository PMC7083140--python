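"""Imaging chain: attenuation, deconvolution, segmentation, and dTT."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import myoslice as ms

from conftest import masks_from_truth

VOX = (0.1, 0.1, 0.1)


def _uniform_stack(value=50.0, shape=(32, 16, 16), atten=0.0):
    img = np.full(shape, value)
    if atten:
        depth = (np.arange(shape[0]) * VOX[0])[:, None, None]
        img = img * np.exp(-atten * depth)
    return ms.VoxelStack(img, VOX)


class TestAttenuation:
    def test_recovers_known_coefficient(self):
        stack = _uniform_stack(atten=0.02)
        assert ms.estimate_attenuation(stack) == pytest.approx(0.02, abs=0.002)

    def test_correction_flattens_plane_means(self):
        stack = _uniform_stack(atten=0.01)
        out = ms.correct_attenuation(stack)
        means = out.intensities.reshape(out.shape[0], -1).mean(axis=1)
        assert np.ptp(means) / means.mean() < 0.02

    def test_near_identity_without_attenuation(self):
        stack = _uniform_stack(atten=0.0)
        out = ms.correct_attenuation(stack)
        assert np.allclose(out.intensities, stack.intensities, rtol=0.01)

    def test_degenerate_inputs(self):
        with pytest.raises(ms.InvalidSpecError):
            ms.estimate_attenuation(_uniform_stack(shape=(4, 8, 8)))
        with pytest.raises(ms.DegenerateInputError):
            ms.estimate_attenuation(_uniform_stack(value=0.0))


class TestDeconvolve:
    def test_zero_iterations_zero_sigma_is_identity(self):
        stack = _uniform_stack()
        out = ms.denoise_deconvolve(stack, psf_sigma_um=(0, 0, 0), iterations=0)
        np.testing.assert_array_equal(out.intensities, stack.intensities)

    def test_contrast_increases_and_flux_conserved(self):
        # two blurred points: RL must monotonically restore peak-to-valley contrast
        from scipy.ndimage import gaussian_filter

        img = np.zeros((24, 24, 24))
        img[12, 12, 8] = img[12, 12, 16] = 1000.0
        img = gaussian_filter(img, 2.0) + 1.0
        stack = ms.VoxelStack(img, VOX)

        def contrast(s):
            peak = s.intensities[12, 12, 8]
            valley = s.intensities[12, 12, 12]
            return peak / valley

        prev = 0.0
        for it in (1, 5, 10):
            out = ms.denoise_deconvolve(stack, psf_sigma_um=(0.2, 0.2, 0.2), iterations=it)
            c = contrast(out)
            assert c > prev
            prev = c
            assert out.intensities.sum() == pytest.approx(img.sum(), rel=0.01)
        assert prev > contrast(stack)  # sharper than the blurred input

    def test_negative_sigma_rejected(self):
        with pytest.raises(ms.InvalidSpecError):
            ms.denoise_deconvolve(_uniform_stack(), psf_sigma_um=(-0.1, 0.1, 0.1))


class TestSegmentMembrane:
    def test_bimodal_fraction_recovered(self):
        rng = np.random.default_rng(0)
        truth = rng.random((32, 32, 32)) < 0.2
        img = np.where(truth, 100.0, 10.0) + rng.normal(0, 2, truth.shape)
        mask = ms.segment_membrane(ms.VoxelStack(np.clip(img, 0, None), VOX))
        assert mask.mean() == pytest.approx(0.2, abs=0.02)

    def test_noiseless_phantom_exact(self, lattice_phantom):
        spec, stack, truth = lattice_phantom
        mask = ms.segment_membrane(stack)
        np.testing.assert_array_equal(mask, truth.tubule_mask | truth.surface_mask)

    def test_dark_polarity_is_complement(self):
        rng = np.random.default_rng(1)
        img = np.where(rng.random((16, 16, 16)) < 0.3, 100.0, 10.0)
        stack = ms.VoxelStack(img, VOX)
        np.testing.assert_array_equal(
            ms.segment_membrane(stack, polarity="dark"), ~ms.segment_membrane(stack)
        )

    def test_constant_stack_rejected(self):
        with pytest.raises(ms.DegenerateInputError):
            ms.segment_membrane(_uniform_stack())


class TestCellMask:
    def test_fallback_fills_membrane_interior(self, lattice_phantom):
        spec, stack, truth = lattice_phantom
        cell = ms.build_cell_mask(stack)
        jac = (cell & truth.cell_mask).sum() / (cell | truth.cell_mask).sum()
        assert jac >= 0.95

    def test_full_frame_marker_yields_frame_minus_border(self):
        stack = _uniform_stack(value=10.0, shape=(16, 16, 16))
        marker = ms.VoxelStack(np.full((16, 16, 16), 80.0), VOX)
        mask = ms.build_cell_mask(stack, marker_stack=marker)
        assert mask[1:-1, 1:-1, 1:-1].all()
        assert not mask[0].any() and not mask[-1].any()

    def test_marker_channel_segmentation(self, lattice_phantom):
        spec, stack, truth = lattice_phantom
        marker_img = np.where(truth.cell_mask, 90.0, 5.0)
        cell = ms.build_cell_mask(stack, marker_stack=ms.VoxelStack(marker_img, VOX))
        jac = (cell & truth.cell_mask).sum() / (cell | truth.cell_mask).sum()
        assert jac >= 0.95


class TestExtractTsystem:
    def test_surface_only_phantom_yields_empty_tubules(self):
        spec = ms.TubulePhantomSpec(cell_extent_um=(5.8, 5.8, 5.8), geometry="surface-only")
        _, truth = ms.gen_tsystem_stack(spec)
        membrane = truth.surface_mask
        with pytest.warns(UserWarning):
            masks = ms.extract_tsystem(membrane, truth.cell_mask, VOX)
        assert masks.empty_tubules and not masks.tubule_mask.any()

    def test_zero_margin_keeps_all_intracellular_membrane(self, lattice_phantom):
        spec, _, truth = lattice_phantom
        membrane = truth.tubule_mask | truth.surface_mask
        masks = ms.extract_tsystem(membrane, truth.cell_mask, VOX, surface_margin_um=0.0)
        np.testing.assert_array_equal(masks.tubule_mask, membrane & truth.cell_mask)

    def test_lattice_recall_against_truth(self, lattice_phantom):
        spec, _, truth = lattice_phantom
        membrane = truth.tubule_mask | truth.surface_mask
        masks = ms.extract_tsystem(membrane, truth.cell_mask, VOX, surface_margin_um=0.2)
        recall = (masks.tubule_mask & truth.tubule_mask).sum() / truth.tubule_mask.sum()
        assert recall >= 0.9

    def test_partition_is_exhaustive(self, lattice_phantom):
        spec, _, truth = lattice_phantom
        membrane = truth.tubule_mask | truth.surface_mask
        masks = ms.extract_tsystem(membrane, truth.cell_mask, VOX, surface_margin_um=0.3)
        np.testing.assert_array_equal(
            masks.tubule_mask | masks.surface_mask, membrane & truth.cell_mask
        )


class TestComputeDtt:
    def test_tubules_everywhere_gives_zero(self):
        m = np.ones((8, 8, 8), dtype=bool)
        masks = ms.SegmentationMasks(m, m, m, np.zeros_like(m))
        assert ms.compute_dtt(masks, VOX).delta_tt_um == 0.0

    def test_empty_tubules_flagged_nan_not_raised(self):
        cell = np.ones((8, 8, 8), dtype=bool)
        z = np.zeros_like(cell)
        metrics = ms.compute_dtt(ms.SegmentationMasks(z, cell, z, z), VOX)
        assert metrics.empty_tubules and math.isnan(metrics.delta_tt_um)

    def test_sheet_spacing_gives_quarter_spacing(self, sheet_phantom):
        spec, _, truth = sheet_phantom
        metrics = ms.compute_dtt(masks_from_truth(truth), VOX)
        assert metrics.delta_tt_um == pytest.approx(0.25, abs=0.01)

    def test_doubling_spacing_doubles_dtt(self):
        vals = {}
        for spacing in (1.0, 2.0):
            spec = ms.TubulePhantomSpec(
                cell_extent_um=(5.8, 8.0, 8.0), geometry="sheets", lattice_spacing_um=spacing
            )
            _, truth = ms.gen_tsystem_stack(spec)
            vals[spacing] = ms.compute_dtt(masks_from_truth(truth), VOX).delta_tt_um
        assert vals[2.0] == pytest.approx(2 * vals[1.0], rel=1e-6)

    @pytest.mark.parametrize(
        "geometry,spacing", [("sheets", 1.0), ("sheets", 2.0), ("full-lattice", 1.0), ("full-lattice", 1.8)]
    )
    def test_matches_brute_force_oracle(self, geometry, spacing):
        spec = ms.TubulePhantomSpec(
            cell_extent_um=(5.8, 5.8, 5.8), geometry=geometry, lattice_spacing_um=spacing
        )
        _, truth = ms.gen_tsystem_stack(spec)
        edt = ms.compute_dtt(masks_from_truth(truth), VOX).delta_tt_um
        bf = ms.brute_force_dtt(truth.tubule_mask, truth.cell_mask, VOX)
        assert edt == pytest.approx(bf, rel=0.01)

    def test_random_tubule_mask_matches_brute_force(self):
        rng = np.random.default_rng(4)
        cell = np.zeros((20, 20, 20), dtype=bool)
        cell[2:-2, 2:-2, 2:-2] = True
        tub = cell & (rng.random(cell.shape) < 0.01)
        masks = ms.SegmentationMasks(tub, cell, tub, np.zeros_like(tub))
        edt = ms.compute_dtt(masks, VOX).delta_tt_um
        bf = ms.brute_force_dtt(tub, cell, VOX)
        assert edt == pytest.approx(bf, rel=0.01)

    @given(k=st.floats(min_value=0.25, max_value=4.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_equivariance(self, k):
        spec = ms.TubulePhantomSpec(
            cell_extent_um=(5.8, 5.8, 5.8), geometry="sheets", lattice_spacing_um=1.0
        )
        _, truth = ms.gen_tsystem_stack(spec)
        masks = masks_from_truth(truth)
        base = ms.compute_dtt(masks, VOX, keep_distance_map=False).delta_tt_um
        scaled = ms.compute_dtt(
            masks, tuple(k * v for v in VOX), keep_distance_map=False
        ).delta_tt_um
        assert scaled == pytest.approx(k * base, rel=1e-9)

    def test_deleting_tubules_never_decreases_dtt(self, sheet_phantom):
        spec, _, truth = sheet_phantom
        rng = np.random.default_rng(0)
        masks = masks_from_truth(truth)
        base = ms.compute_dtt(masks, VOX, keep_distance_map=False).delta_tt_um
        tub = truth.tubule_mask.copy()
        prev = base
        for frac in (0.2, 0.5, 0.9):
            keep = rng.random(tub.shape) > frac
            reduced = truth.tubule_mask & keep
            masks_r = ms.SegmentationMasks(
                masks.membrane_mask, masks.cell_mask, reduced, np.zeros_like(reduced)
            )
            val = ms.compute_dtt(masks_r, VOX, keep_distance_map=False).delta_tt_um
            assert val >= prev - 1e-12
            prev = val


class TestAggregate:
    def _metric(self, v):
        return ms.TSystemMetrics(delta_tt_um=v, per_stack_values=(v,), n_stacks=1)

    def test_mean_of_three_stacks(self):
        out = ms.aggregate_sample_dtt([self._metric(v) for v in (0.9, 1.1, 1.0)])
        assert out.delta_tt_um == pytest.approx(1.0)
        assert out.n_stacks == 3 and not out.low_n

    def test_single_stack_warns_low_n(self):
        with pytest.warns(UserWarning):
            out = ms.aggregate_sample_dtt([self._metric(0.8)])
        assert out.delta_tt_um == pytest.approx(0.8) and out.low_n

    def test_permutation_invariant(self):
        vals = [0.7, 1.3, 1.1, 0.95]
        a = ms.aggregate_sample_dtt([self._metric(v) for v in vals])
        b = ms.aggregate_sample_dtt([self._metric(v) for v in vals[::-1]])
        assert a.delta_tt_um == b.delta_tt_um

    def test_empty_rejected(self):
        with pytest.raises(ms.InvalidSpecError):
            ms.aggregate_sample_dtt([])


class TestEndToEnd:
    @pytest.mark.parametrize("spacing", [0.8, 1.4, 2.0])
    def test_noisy_chain_recovers_true_dtt_within_10pct(self, spacing):
        spec = ms.TubulePhantomSpec(
            cell_extent_um=(5.8, 10.0, 10.0),
            geometry="full-lattice",
            lattice_spacing_um=spacing,
            tubule_radius_um=0.15,
            blur_sigma_um=0.1,
            attenuation_coefficient_per_um=0.01,
            noise_sigma=5.0,
            rng_seed=11,
        )
        stack, truth = ms.gen_tsystem_stack(spec)
        true_val = ms.brute_force_dtt(truth.tubule_mask, truth.cell_mask, VOX)
        st = ms.correct_attenuation(stack)
        st = ms.denoise_deconvolve(st, psf_sigma_um=(0.1, 0.1, 0.1), iterations=5)
        membrane = ms.segment_membrane(st)
        cell = ms.build_cell_mask(st)
        masks = ms.extract_tsystem(membrane, cell, VOX)
        measured = ms.compute_dtt(masks, VOX, keep_distance_map=False, domain="interior")
        assert measured.delta_tt_um == pytest.approx(true_val, rel=0.10)
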