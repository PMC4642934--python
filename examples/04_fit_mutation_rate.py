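"""Fit the mutation rate of one synthetic data set end to end.

Simulates four diploid genomes with a known true rate, builds matched
calibration curves by coalescent simulation at mu = 1, 2, 4 x 1e-8 under
a freshly perturbed map, fits mu by variance-weighted least squares, and
reports the leave-one-chromosome jackknife standard error.
"""

import dataclasses

from mucal import run_trial, scale_profile, scenario_genomes

profile = dataclasses.replace(scale_profile("desk"), n_chrom=10,
                              chrom_length=3_000_000, calib_region_cap=100)
data = scenario_genomes("baseline", seed=21, n_genomes=profile.n_genomes,
                        n_chrom=profile.n_chrom,
                        chrom_length=profile.chrom_length)
result = run_trial(data, profile, seed=22)

print(f"true rate:    {result.mu_true:.2e}")
print(f"fitted rate:  {result.mu_raw:.3e} per base per generation")
print(f"jackknife SE: {result.jackknife_se:.1e}")
print(f"starting points: {result.n_points}   "
      f"H_S(0) = {result.details['h0']:.2e}")
print()
print("The fitted rate should lie within roughly two standard errors of "
      "the true 2.5e-8; the jackknife treats each chromosome as one "
      "observation, which absorbs the long-range coalescent correlations.")
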