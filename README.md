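# myoslice

Structure–function analysis of living myocardial slices from failing human
hearts, as a tested Python library with a fully synthetic, ground-truthed
data layer.

Ventricular cardiomyocytes conduct the action potential into their interior
through transverse tubules (the t-system). In heart failure the t-system
degrades, and the distance a Ca²⁺ signal must travel from the nearest
membrane grows. This package quantifies that remodeling and relates it to
contractile function:

- **ΔTT** — the mean intracellular distance to the closest t-tubule, from
  the anisotropy-aware 3D Euclidean distance transform of the segmented
  t-tubule signal within the cardiomyocyte mask of a WGA-stained confocal
  stack (attenuation-corrected, Richardson–Lucy deconvolved,
  histogram-thresholded; t-system separated from the outer sarcolemma by a
  configurable surface margin). Per sample, ΔTT is the mean over ≥ 3 stacks.
- **Twitch kinetics and the FFR** — per contraction: peak active force
  F_max, time to peak (TTP), time from peak to 90 % relaxation (TTR), and
  CD₉₀ = TTP + TTR; traces follow a 0.2/0.5/1/2 Hz staircase (120 s per
  interval, last 30 s analysed). The force–frequency relationship is
  summarised as F₁Hz/F₀.₅Hz and F₂Hz/F₀.₅Hz (> 1 positive, < 1 negative),
  and wall tension as T = F/A with A = 5 mm × 0.25 mm = 1.25 mm².
- **Morphometry** — iterative watershed segmentation of myocytes in 2D WGA
  tile scans, long-axis orientation from second-order image moments, axial
  dispersion and the fraction of cells deviating > 30° from the main fiber
  direction; sarcomere length from the 2D power-spectrum maximum within
  1/2.5–1/1.5 µm⁻¹.
- **Statistics** — OLS regressions with F-tests against the constant model
  and 95 % CI bands; the no-intercept interaction model
  `TTR = b₁·(ΔTT − r·NCX1·ΔTT)` with a Gaussian likelihood-ratio test
  (LR = n·ln(RSS₀/RSS₁) ~ χ²) against the ΔTT-only model; dichotomization
  at ΔTT = 1.05 µm (boundary to the severe group); unpaired two-tailed
  Student t-tests with Holm–Bonferroni correction; immunoblot densitometry
  normalized to √(Ponceau·GAPDH) and a per-gel reference.

Because the underlying patient data are not public, a first-class synthetic
module (`myoslice.synth`) generates every input with exact ground truth:
membrane phantoms with analytic mean tubule distances (d/4 for parallel
sheets; (d/6)(√2 + ln(1+√2)) ≈ 0.3826·d for a square lattice of lines),
biexponential twitch staircases with closed-form TTP
(τ_r·τ_d·ln(τ_d/τ_r)/(τ_d−τ_r)), myocyte mosaics with known per-cell
orientations, striation patterns of known period, and cohort tables drawn
from stated generating models.

## Worked example

`examples/cohort_regression.py` generates a 200-sample cohort in which TTR
follows the interaction model with coefficients (0.36, 0.069) plus 5 ms of
noise, then refits it:

```
FFR ~ dTT        : slope -0.780/um, R2 = 0.80, p = 2.87e-71
TTR interaction  : TTR = 0.359*(dTT - 0.0670*NCX1*dTT)   [generated: 0.360, 0.0690]
LRT vs dTT-only  : LR = 598.7, p = 3.21e-132
dTT < 1.05 um    : n = 66,  mean FFR = 1.09
dTT >= 1.05 um   : n = 134, mean FFR = 0.83
group difference : t = 15.2, p = 4.56e-35
```

Both generating coefficients are recovered (0.359 and 0.067 vs 0.36 and
0.069), the FFR declines with remodeling, and samples below the 1.05 µm
threshold keep a positive FFR (1.09) while severely remodeled samples show
a negative one (0.83).

The other examples each exercise one capability and print what they
compute: `phantom_dtt.py` (distance-transform ΔTT vs exhaustive oracle vs
closed form), `imaging_chain.py` (full imaging chain on a noisy, blurred,
attenuated stack), `twitch_ffr.py` (staircase kinetics, FFR, wall tension),
`morphometry_disarray.py` (watershed, disarray, sarcomere length), and
`full_pipeline.py` (the end-to-end synthetic study via
`myoslice.run_pipeline`).

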