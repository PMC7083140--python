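# Methods

This note documents the models, estimators and numerical choices behind
`myoslice`, and what the synthetic data layer does and does not establish.

## T-system remodeling metric (ΔTT)

ΔTT is defined as the mean, over intracellular voxels, of the Euclidean
distance to the nearest t-tubule voxel. It is computed with
`scipy.ndimage.distance_transform_edt` using the stated voxel size as
sampling, so anisotropic stacks are handled exactly; distances are always
reported in µm. Two conventions are configurable:

- **Averaging domain.** By default all cell-mask voxels enter the mean,
  including tubule voxels themselves at distance 0 (`include_tubule_voxels`
  switches this off). A second switch, `domain="interior"`, restricts the
  average to the sub-surface interior over which the t-system was
  extracted. This matters because the surface-separation rule (below)
  reclassifies tubules within the margin as sarcolemma; voxels in that
  shell would then be measured against tubules farther inside and bias ΔTT
  upward, by up to tens of percent when tubule spacing is below ~1 µm. The
  end-to-end pipeline therefore uses the interior domain; the plain
  cell-mask domain remains the default for mask-level analysis.
- **Surface separation.** The t-system is `membrane ∧ cell` deeper than
  `surface_margin_um` (default 0.5 µm) below the cell boundary, measured by
  the distance transform of the cell mask; the remainder is the outer
  sarcolemma. 0.5 µm comfortably exceeds the apparent surface thickness
  after realistic blur; smaller margins let blurred surface signal leak
  into the t-tubule class and bias ΔTT low.

An empty extracted t-system yields a flagged NaN rather than an exception,
so severely remodeled samples flow through cohort-level aggregation
(arithmetic mean over ≥ 3 stacks per sample, with a low-n warning below 3).

**Validation.** `brute_force_dtt` is an independent oracle: an exact
KD-tree nearest-neighbour query over tubule voxel coordinates, sharing no
code with the distance-transform path. On all phantoms the two agree within
1 %. Sheet phantoms have closed-form mean distance d/4 (distance to the
nearest of parallel planes at spacing d is uniform on [0, d/2]); lattice
phantoms (lines along the cell axis on a square d-lattice) have mean
(d/6)(√2 + ln(1+√2)) ≈ 0.38260·d in the radius→0 limit. To make these
attainable on a voxel grid, the generator snaps the spacing to whole voxels,
trims the cell to whole periods and centres tubules at half-period offsets,
so voxel centres sample each period symmetrically; the closed forms are
claimed in the ground truth only for single-voxel (radius→0) tubules, and
NaN otherwise (use the oracle).

## Imaging chain

- **Attenuation.** Depth-dependent signal loss is modelled and corrected as
  a single exponential gain exp(−c·z): c is estimated by least squares on
  log plane means and divided out. This is the simplest model consistent
  with depth-dependent attenuation; it is exact for the synthetic data by
  construction and approximate for real stacks.
- **Deconvolution.** Optional median pre-filter, then Richardson–Lucy
  (`skimage.restoration.richardson_lucy`, clip off) with a Gaussian PSF
  whose (dz, dy, dx) sigmas are given in µm and converted to voxels. RL
  preserves non-negativity and conserves total intensity within ~1 %;
  contrast on a two-point phantom increases monotonically over 1–10
  iterations. Deconvolving an image that was never blurred is mismatched
  and destroys sub-resolution structures, so the pipeline always pairs the
  generator's optical blur (σ = 0.1 µm) with a matching PSF.
- **Segmentation.** Global Otsu threshold ("histogram-based"); a
  fixed-quantile alternative was considered unnecessary for the phantoms.
  Constant images raise a degenerate-input error; an inverted-contrast
  polarity flag returns the complement.
- **Cell mask.** From a marker channel when available (Otsu + closing +
  hole fill); otherwise the filled interior of the membrane mask's outer
  surface — exact for closed-surface phantoms (Jaccard ≥ 0.95).

End-to-end, the chain recovers the oracle ΔTT within ±7 % across tubule
spacings 0.8–5.2 µm under blur, 0.01/µm attenuation and Gaussian read noise
at σ = 5 (5 % of the membrane amplitude).

## Twitch analysis

The synthetic twitch is F(t) = A·(exp(−t/τ_d) − exp(−t/τ_r)) with
τ_d > τ_r > 0. Its time to peak is analytically
τ_r·τ_d·ln(τ_d/τ_r)/(τ_d−τ_r) and its peak value
A·((τ_r/τ_d)^{τ_r/(τ_d−τ_r)} − (τ_r/τ_d)^{τ_d/(τ_d−τ_r)}); TTR (time from
peak to 90 % relaxation) is solved numerically by bracketing. Default
shapes accelerate with pacing rate — (τ_r, τ_d) = (0.05, 0.15) s at
0.2–0.5 Hz down to (0.03, 0.065) s at 2 Hz — so each twitch relaxes to
within 5 % of its peak inside the stimulation period. A residual of even
0.5 % at the next stimulus measurably shifts the 90 %-relaxation crossing
(~5 ms), which drove this choice; genuinely fused twitches are handled by a
flagged intra-beat-minimum baseline but are excluded from the round-trip
guarantees.

Measurement definitions: onset is the stimulus time when known, else the
crossing of baseline + 5 % amplitude; TTP = peak − onset; TTR = peak to
90 % decay with linear interpolation at the crossing; CD₉₀ = TTP + TTR by
construction. The per-interval baseline is the diastolic force — the
median of the samples immediately preceding each stimulus — which is exact
for paced recordings; without stimulus times it falls back to the 10th
percentile of interval force (slightly biased when twitches fill the whole
period, as at 2 Hz). Truncated twitches (peak at a window edge, or no
90 % recovery before the window ends) are flagged and excluded from
interval means. On noiseless staircases the recovered TTP is within one
1 kHz sample of the closed form at every protocol frequency, F_max within
0.5 %, and programmed FFR ratios within 0.5 %.

Wall tension divides force by the effective slice cross-section
width × (nominal thickness − damaged margin), default
5 × (0.3 − 0.05) mm = 1.25 mm². Per-sample summaries are component-wise
medians across 2–8 slices.

## Morphometry

Watershed segmentation follows the published recipe: threshold the WGA
image (Otsu), distance-transform the complement, flood the negated
distance transform from seeds, then iteratively delete segments with low
boundary contact to the WGA mask (< 0.6 of the boundary) or area < 50 µm²
and re-run until stable (≤ 5 rounds). Seeding uses ridge pixels within 70 %
of each connected component's distance maximum rather than raw regional
maxima: the distance ridge of an elongated cell is flat, and floating-point
regional maxima fragment it into multiple seeds (oversegmentation), whereas
the ridge-fraction rule yields one seed per cell body while still
separating cells joined by thin bridges.

Orientation is the angle of the dominant eigenvector of each segment's
second-order central moment matrix, in image coordinates (from the x/column
axis toward +y/rows), axial range [−90°, 90°). Segments with eigenvalue
ratio < 1.05 (near-isotropic) are flagged undefined. The main fiber
orientation is the doubled-angle circular mean; dispersion is the SD of
axial deviations about zero (the plain SD of signed deviations is also
reported, since either convention is defensible); disarray is the fraction
deviating > 30°. The mosaic generator draws exactly
round(f·n) cells with offsets in (36°, 60°) and clips aligned scatter at
25°, so the programmed disarray fraction is exact by construction and
estimation error cannot move cells across the 30° criterion.

Sarcomere length: Hann window, 2× zero-padded 2D FFT, dominant non-DC
power-spectrum peak refined by parabolic interpolation of log power along
both frequency axes (rotation-invariant to within 0.02 µm). The global
(non-DC) peak must fall inside the 1/2.5–1/1.5 µm⁻¹ band and exceed 10× the
in-band median power, otherwise the result is flagged undefined — an
out-of-band striation is never silently clipped into the band.

## Statistical layer

Univariate fits are ordinary least squares (statsmodels) with R², the
F-statistic against the intercept-only model, and pointwise 95 % CI bands
for the mean response. The relaxation-time model is fitted without
intercept, `TTR ~ ΔTT + ΔTT:NCX1`, and reported in the factored form
b₁·(ΔTT − r·NCX1·ΔTT), r = −b₂/b₁; R² then uses the uncentred total sum of
squares, recorded as such in the output. The likelihood-ratio test uses the
Gaussian closed form LR = n·ln(RSS_reduced/RSS_full) against χ² with the
coefficient-count difference as df; nested least squares guarantees
RSS_full ≤ RSS_reduced, and a violation raises an internal-consistency
error. Monte-Carlo calibration at n = 100 under the no-interaction null
gives a type-I error of 0.046 at α = 0.05 (1000 replicates).

Group comparisons use the classic equal-variance Student t-test (two-tailed,
unpaired; Welch available), with Holm–Bonferroni step-down adjustment
across the four pacing frequencies. The ΔTT dichotomization assigns the
boundary value 1.05 µm to the severe group. Densitometry normalization is
raw / √(Ponceau·GAPDH) / reference, where the reference is the same-gel
reference lane's own loading-normalized value; the result is invariant to
per-gel exposure scaling.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* of the study's data — geometry,
protocols, noise processes, and the stated generating relationships (ΔTT
uniform over the observed 0.8–1.5 µm range; NCX1 over 0.2–3.0; the
interaction model with coefficients 0.36 and 0.069; FFR declining linearly
in ΔTT with unity crossing near 1.05 µm, giving group means near 1.08 and
0.80). They do not emulate real tubule tortuosity, clustered vs uniform
tubule loss (unknown; both placements are expressible via spacing and the
custom-mask geometry), nuclei, fibrosis, optical PSF structure beyond a
Gaussian, or biophysical Ca²⁺ handling. Passing tests therefore establish
correctness of the estimators on data of known structure, not performance
on real tissue.

Default problem sizes are desk-scale by design: 64³–134×134×64-voxel stacks
at 0.1 µm (full-size 1280×1280×300 stacks are expressible via the spec),
6-sample pipeline cohorts with 3 stacks and 2 slices each, 100-cell
mosaics, and 200-sample cohorts for regression recovery. A full pipeline
run takes ~20 s on one CPU.

## Known limitations

- The exponential attenuation model is a deliberate simplification; real
  depth-dependent attenuation is specimen-dependent.
- ΔTT from segmented (finite-radius) tubules sits roughly one tubule radius
  below the radius→0 closed form; the pipeline's spacing choice compensates
  when mapping target ΔTT to phantom spacing.
- The 90 % level defining TTR (and hence CD₉₀ = TTP + TTR) is one reading
  of schematic definitions; both thresholds are configurable
  (`ttr_recovery`).
- With stimulus times absent, baseline estimation degrades at high pacing
  rates where the trace never rests at diastole.
- The interaction-ratio estimator −b₂/b₁ has a sampling SD of ~1.4 % at
  n = 200, noise 0.005 s; single-cohort recoveries scatter accordingly.
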