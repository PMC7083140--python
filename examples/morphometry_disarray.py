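"""Myocyte disarray and sarcomere length on synthetic 2D scans.

Segments a WGA-like mosaic of elongated myocytes with the iterative
watershed, measures each cell's long-axis orientation from image moments,
summarises disarray, and estimates sarcomere length from the band-limited
power spectrum of a striated pattern.
"""
import myoslice as ms

img, truth = ms.gen_myocyte_mosaic(
    n_cells=100, angle_sd_deg=12.0, disarray_fraction=0.11, rng_seed=1, noise_sd=5.0
)
seg = ms.watershed_segment(img, pixel_size_um=1.0)
orientations = ms.segment_orientation(seg)
stats = ms.orientation_stats(orientations)

print(f"cells segmented        : {seg.n_cells} (truth: 100)")
print(f"main fiber orientation : {stats.main_orientation_deg:+.1f} deg")
print(f"dispersion (axial SD)  : {stats.dispersion_deg:.1f} deg")
print(f"disarray fraction >30  : {stats.disarray_fraction:.1%} (programmed 11%)")

pattern = ms.gen_sarcomere_pattern(2.05, angle_deg=25.0, noise_sd=10.0, rng_seed=2)
sl = ms.sarcomere_length(pattern, pixel_size_um=0.1)
print(f"sarcomere length       : {sl.length_um:.3f} um (programmed 2.050 um)")
# Dispersion near 19 deg with ~11% of cells off-axis matches the disarray
# level of failing human myocardium; diastolic sarcomere length ~2 um.
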