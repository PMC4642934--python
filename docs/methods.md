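# Methods

## Model and procedure

The package estimates the per-generation point-mutation rate μ of diploid
genomes from the joint information in local heterozygosity and the
recombination map.  Heterozygosity at a locus is 2*T*μ in expectation for
pair-coalescence time *T*; the physical scale over which heterozygosity
decorrelates is set by the recombination rate *r* through the ancestral
block length (2*Tr*)⁻¹.  The procedure:

1. **Genotype calling and masking** (`genomic_io`).  A site is called
   heterozygous only when the heterozygote genotype likelihood beats the
   better homozygote by Q + P PL units (defaults Q = 60, P = 31, the
   prior offset reflecting genome-average heterozygosity), homozygous
   when the homozygote wins by Q − P, and masked in between.  External
   masks (tandem-repeat, alignability), a per-genome coverage mask
   (central 95% of the depth distribution, nearest-rank convention), and
   the quality-band mask are pooled and dilated by 2 bp.  Multi-allelic
   sites are masked: the model is strictly biallelic.
2. **Ascertainment** (`ascertainment`).  The genome is tiled with 100-kb
   windows per genome; windows with more than half their sites masked are
   unusable.  Windows whose heterozygous-site count lies in the closed
   range S (default 5–10) and with at least one heterozygous site in each
   half become starting points at their midpoints.  Around each point a
   super-region extends to at least 0.1 cM of base-map distance on both
   sides; points whose flank would cross a chromosome end are dropped.
3. **The statistic** (`hs`).  H_S(d) is pooled heterozygosity (summed
   heterozygous sites over summed unmasked sites, across genomes and
   regions) in 60 half-open bins over (0, 0.1] cM of base-map distance
   from the midpoints, both directions pooled; a site exactly at 0.1 cM
   is excluded.  The d = 0 anchor is the pooled heterozygosity of the
   ascertained windows themselves.
4. **Calibration** (`coalescent`, `harness`).  Each super-region is
   simulated independently with the exact (Hudson) coalescent with
   recombination — the TMRCA sequence along a chromosome is not
   Markovian, and SMC-class approximations distort precisely the
   long-range structure the statistic measures.  Only θ = 4Nμ and the
   size history in coalescent units are identifiable from data, so a
   calibration run at rate μ_c uses N_c = θ/(4μ_c) with epoch times
   scaled by N_c/N: this preserves θ and sets ρ = θr/μ_c.  Simulated
   genomes pass through the same ascertainment rule; distances are always
   measured on the base map while simulation uses a perturbed map (below).
5. **Fitting** (`estimator`).  Per bin, the calibration family H(d; μ) is
   interpolated across the grid (default μ = 1, 2, 4 × 10⁻⁸) and the
   observed curve is matched by variance-weighted least squares over bins
   1–60 (the anchor is fixed by ascertainment on both sides), minimized
   by a dense grid plus bounded refinement (tolerance 10⁻¹³ on μ).
6. **Corrections** (`corrections`), applied in fixed order: multiply by
   (H_S(0) − ε)/H_S(0); subtract c·(r_local/r_genome)·(H̄ − H_S(0))/2;
   multiply by the base-content mutability factor.  With all three
   disabled the corrected rate equals the raw fit.
7. **Uncertainty**.  Weighted delete-one-chromosome jackknife (block
   weights = starting points per chromosome, Busing-type formula; each
   deletion recomputes the observed curve, the calibration curves, the
   asymptote adjustment, and the corrections from per-chromosome
   accumulators).  Parameter uncertainties (α by regression of μ̂ on an α
   grid times SE_α; ε by counting error; c from its CI) are combined with
   the jackknife by root-sum-of-squares under an independence assumption.

## Map-error model

For a grid interval with observed genetic length g (Morgans) and physical
length p (bases), the true length is modelled as Z ∼ Gamma(αg′, α) with
g′ = γ(g + πp), so E[Z] = g′ and var(Z) = g′/α.  Defaults: α = 3100 M⁻¹
(SE 300) for real data, α = 3000 M⁻¹ in the simulation scenarios;
π = 0.09 cM/Mb compensates the under-estimation of very short intervals
(zero-length intervals in published maps are mostly sampling zeros);
γ = G/(G + πP) is computed genome-wide and preserves the total map
length.  1/α ≈ 0.03 cM is the interval length at which the map's
coefficient of variation reaches 1.  Calibration runs draw one fresh
perturbed map per replicate; the test-data generator likewise draws a
single "true" map per data set, so data and calibration see identically
distributed map error relative to the base map.  Assembly gaps are not
modelled in the synthetic maps, so no cap on the prior mass of very long
physical intervals is applied.

## Asymptote adjustment

Residual mismatch between the data's and the calibration's mean
heterozygosity would misalign the curve asymptotes, so the relaxation
portion of each calibration curve is rescaled:
H′(d) = H(0) + (H(d) − H(0)) · H̄_data/H̄_sim.  Both references are
span means over the super-regions computed **excluding the ascertained
genome**: the owner is conditioned low by ascertainment (and, through the
shared ancestral graph, so is any co-sampled genome at that locus — a
~13% pull at the scales used here), and the exclusion is applied
identically on both sides, making the ratio an unbiased match by
construction (verified by a dedicated matching experiment).  The
simulated reference pools the grid curves, as the span mean is invariant
under the θ-preserving rescaling.  Ratios outside [0.5, 2] raise a
warning; in well-matched runs the adjustment is within ~10%.

## Numerical choices

- **Interpolation coordinate.**  The curve family is nearly linear in
  x = 1/μ (heights track the starting-point TMRCA ∝ 1/μ at fixed θ).
  The fitted family is piecewise linear in x through the grid curves —
  exact at grid points, monotone, and free of the overshoot a cubic in
  linear μ exhibits across the sparse geometric grid, which measurably
  biased interior fits upward.  A not-a-knot cubic spline in x is
  available (`fit_mu(..., interpolation="spline")`); the two agree to a
  few percent on smooth families.
- **Weights.**  The per-bin weights use a smooth variance model
  H(d)/n_sites(d), with the level taken from the (smoothed) calibration
  family mean.  Empirical leave-one-chromosome bin variances are
  computed (`HSCurve.bin_variances`) and used for reporting, but at
  reduced scale they correlate with each bin's own fluctuation —
  variance tracks the level of a ratio — which up-weights
  downward-fluctuating bins and biases the fit.
- **Envelope check.**  The fit aborts ("extrapolation") only when the
  observed curve escapes the calibration envelope on **one side** in more
  than half the bins; symmetric excursions are bin noise.  The linear
  family extends linearly slightly beyond the grid so near-envelope fits
  resolve rather than saturate.
- **Calibration pooling.**  Within a trial, independent calibration
  replicates (fresh perturbed map and simulations each) are pooled into
  one curve set before fitting; pooling integrates over map-perturbation
  randomness with less noise-convexity bias than averaging separate fits
  at small curve counts.  `average_calibrations` implements the
  average-of-fits used for final point estimates on real data.
- **Degenerate inputs.**  Zero or missing bin variances are replaced by
  the minimum positive variance (with a warning); chromosomes without
  starting points simply drop out of the jackknife; a super-region of
  zero genetic length is an error.

## Synthetic-data generator

`scenario_genomes` emulates the validation design: diploid genomes
simulated chromosome-by-chromosome under a 10× bottleneck from 1000 to
2000 generations ago (ancestral size 10,000 with μ = 2.5 × 10⁻⁸, or
16,666 with μ = 1.5 × 10⁻⁸, keeping θ = 10⁻³), under a synthetic
heterogeneous SNP-grid map (2-kb grid, lognormal interval rates around
1.25 cM/Mb with 10% zero-length intervals, mimicking admixture-based
maps) perturbed once with α = 3000 M⁻¹.  Scenario variants add
non-crossover gene conversion (c = 5.9 × 10⁻⁶ per base per diploid
generation, geometric tracts of mean 100 bp), injected false
heterozygotes (1 per 100 kb, or 1 per 150 kb in the combined scenario),
window-level mutation-rate multipliers (lognormal, CV 0.3 — a stand-in
for empirically observed regional rate variation), and admixture (two
populations splitting 3000 generations ago, merging 100 generations ago
with equal proportions).  The gene-conversion rate is read as a
*per-diploid-generation* involvement probability — the convention under
which the published subtraction formula and direct coalescent simulation
agree — so the per-lineage initiation rate passed to msprime is
c/(2 × tract length).

What the generator does **not** emulate: nucleotide sequence context
(sites are abstract biallelic positions, so CpG-based error estimation
and base-content factors are exercised on constructed inputs rather than
in scenario runs), missing data and per-genome masks, reference bias,
and PSMC inference noise (the true demography, known to the generator,
is passed to calibration — PSMC output can be supplied for real data via
`parse_psmc`).  Passing tests therefore demonstrate the method's own
consistency under its model, not robustness to artifacts absent from the
generator.

## Problem sizes

The `full` scale profile records the full validation-study conditions (20 genomes,
25 trials, 30 simulated genomes per calibration curve); running it takes
hours.  The `desk` profile — 4 genomes, 16 chromosome segments of 4 Mb,
5 trials, 10 genomes per curve over up to 140 super-regions, 2 pooled
calibrations — yields ~200–300 starting points per trial and completes a
scenario in under two minutes on one CPU (gene-conversion scenarios are
a few times slower).  At this scale the recovery checks use the realized
spread across trials as their yardstick (estimates within two standard
errors of the trial mean), and per-trial jackknife standard errors run
conservative relative to the realized spread, as intended.

## Known limitations

- The CpG/non-CpG class mode (`class_partition`) supplies the partition,
  class-specific ascertainment ranges (0.1–2 and 4.375–8.75), the reduced
  CpG calibration grid, ε scaling by class site fraction, and the
  GC-bias-adjusted gene-conversion split (0.09/0.91); end-to-end class
  estimates additionally require sequence-context-aware data.
- The base-content mutability score 1 + 9·f_CpG + 0.4·f_GC +
  0.5·f_CpG·f_GC encodes ~10× CpG-transition mutability with modest GC
  and interaction effects; the coefficients are configurable stand-ins
  validated by sign and magnitude checks, not a fitted mutability model.
- GC-biased transmission in gene conversion is ignored except through
  the class-mode split, which is conservative for the correction.
- At desk scale a small upward residual (~2% on the baseline) remains
  from noise in the calibration family interacting with the convex μ
  spacing; it shrinks with the number of starting points and is well
  inside the recovery tolerances.
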