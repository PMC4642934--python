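"""A reduced simulation study: recovery with genotype errors.

Injects false heterozygous sites at 1 per 100 kb into simulated genomes,
runs the full pipeline over independent trials, and applies the
(H_S(0) - eps)/H_S(0) correction with a directly counted error rate.
The summary compares the realized spread of the estimates with the mean
jackknife standard error.
"""

from mucal import run_scenario

table, summary = run_scenario("genotype_error", n_trials=3, profile="desk",
                              seed=9)

print(f"true rate            : {summary['mu_true']:.2e}")
print(f"mean raw fit         : {summary['mean_mu_raw']:.3e}  (inflated by errors)")
print(f"mean corrected fit   : {summary['mean_mu_corrected']:.3e}")
print(f"SD across trials     : {summary['sd_mu_corrected']:.1e}")
print(f"mean jackknife SE    : {summary['mean_jackknife_se']:.1e}")
print()
print("The raw fit overshoots because false heterozygotes mimic extra "
      "mutations; the counted-error correction pulls the estimate back "
      "to the truth. The jackknife SE should be comparable to (and on "
      "average more conservative than) the realized SD.")
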