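"""Structure-function regression on a synthetic patient cohort.

Generates a cohort in which the FFR declines linearly with t-system
remodeling (dTT) and relaxation time follows the no-intercept interaction
model TTR = b1*(dTT - r*NCX1*dTT). Refits both models, runs the
likelihood-ratio test of the interaction against the dTT-only model, and
dichotomizes the cohort at dTT = 1.05 um.
"""
import numpy as np

import myoslice as ms

cohort, truth = ms.gen_cohort(n_samples=200, ttr_noise_sd=0.005, rng_seed=1)
d = cohort["delta_tt_um"].to_numpy()
ncx1 = cohort["ncx1"].to_numpy()
ttr = cohort["ttr_1hz_s"].to_numpy()

lin = ms.linear_fit(d, cohort["ffr_1_0p5"].to_numpy())
print(f"FFR ~ dTT        : slope {lin.params[1]:+.3f}/um, R2 = {lin.r2:.2f}, p = {lin.p_value:.2e}")

full = ms.interaction_fit(d, ncx1, ttr)
reduced = ms.interaction_fit(d, np.zeros_like(ncx1), ttr)
lr, p = ms.likelihood_ratio_test(full, reduced)
print(f"TTR interaction  : TTR = {full.reparam['b1']:.3f}*(dTT - "
      f"{full.reparam['interaction_ratio']:.4f}*NCX1*dTT)   [generated: 0.360, 0.0690]")
print(f"LRT vs dTT-only  : LR = {lr:.1f}, p = {p:.2e}")

low, high = ms.dichotomize_by_dtt(cohort)
print(f"dTT < 1.05 um    : n = {len(low)},  mean FFR = {low['ffr_1_0p5'].mean():.2f}")
print(f"dTT >= 1.05 um   : n = {len(high)}, mean FFR = {high['ffr_1_0p5'].mean():.2f}")
t, p = ms.t_test_unpaired(low["ffr_1_0p5"], high["ffr_1_0p5"])
print(f"group difference : t = {t:.1f}, p = {p:.2e}")
# Low-remodeling samples keep a positive FFR (>1); severe remodeling
# inverts it -- the structural basis of the functional decline.
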