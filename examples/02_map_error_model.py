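"""The gamma model of genetic-map error.

A published recombination map measures each interval's genetic length
with noise.  The model draws the "true" length of an interval with
observed length g (and physical length p) as

    Z ~ Gamma(shape = alpha*g', rate = alpha),  g' = gamma*(g + pi*p)

so E[Z] = g' and var(Z) = g'/alpha.  The pseudo-count prior pi keeps
zero-length intervals from being pinned at zero, and gamma preserves the
total map length.  1/alpha is the interval size at which the map's
coefficient of variation reaches 1.
"""

import numpy as np

from mucal import MapErrorModel, interpret_alpha, perturb, synthetic_map

model = MapErrorModel(alpha=3100.0, pi_cm_per_mb=0.09)
print(f"alpha = {model.alpha:.0f} M^-1  ->  length scale 1/alpha = "
      f"{interpret_alpha(model.alpha):.3f} cM")

gmap = synthetic_map({"chr1": 2_000_000, "chr2": 2_000_000}, seed=1)
print(f"base map: {gmap.total_cm:.2f} cM over {gmap.total_mb:.1f} Mb "
      f"(mean {gmap.mean_rate_cm_per_mb():.2f} cM/Mb)")
print(f"length-preserving factor gamma = {model.gamma_factor(gmap):.4f}")

totals = [perturb(gmap, model, seed).total_cm for seed in range(200)]
print(f"perturbed total length over 200 draws: "
      f"{np.mean(totals):.2f} +- {np.std(totals):.2f} cM "
      f"(parent {gmap.total_cm:.2f} cM)")
print()
print("Each draw is one plausible 'true' map; calibration data are "
      "simulated under such draws so that map error affects the "
      "calibration curves exactly as it affects the real data.")
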