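"""Post-fit corrections: genotype error, gene conversion, base content.

The raw fitted rate counts every called heterozygous site as a mutation.
Three adjustments, applied in a fixed order, isolate the mutational
signal:

1. multiply by (H_S(0) - eps) / H_S(0), removing the share of false
   heterozygotes (error rate eps per base) in the ascertained windows;
2. subtract the contribution of non-crossover gene conversion,
   c * (r_local/r_genome) * (Hbar - H_S(0)) / 2 : each base lies in a
   conversion tract with probability c per generation (adjusted for the
   local recombination rate), and a tract copying one of the two donor
   haplotypes introduces a polymorphism with probability equal to half
   the excess of genome-average over region heterozygosity;
3. multiply by a base-content mutability factor converting the rate for
   the ascertained regions' composition to a genome-wide equivalent.

The error rate eps can be estimated from the data itself by exploiting
the ~10x elevated mutability of CpG transitions: genuine heterozygous
sites are strongly enriched for CpG transitions while errors are not, so
a diluted CpG fraction in low-heterozygosity regions measures the error
load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CorrectionParams",
    "genotype_error_factor",
    "gene_conversion_subtraction",
    "estimate_genotype_error_cpg",
    "base_content_factor",
    "class_partition",
    "ClassModeSettings",
]


@dataclass
class CorrectionParams:
    """Parameters of the three corrections (real-data defaults)."""

    epsilon: float = 1.08e-5          # false-het rate per base
    epsilon_se: float = 0.28e-5
    gene_conversion_per_base: float = 5.9e-6
    gene_conversion_ci: tuple = (4.6e-6, 7.4e-6)   # 95% CI
    rate_ratio: float = 1.0           # local / genome recombination rate
    beta_cpg: float = 9.0             # CpG transitions ~10x as mutable
    beta_gc: float = 0.4
    beta_interaction: float = 0.5
    class_mode: bool = False

    def __post_init__(self):
        if self.epsilon < 0 or self.gene_conversion_per_base < 0:
            raise ValueError("rates must be >= 0")

    @property
    def gene_conversion_se(self) -> float:
        lo, hi = self.gene_conversion_ci
        return (hi - lo) / (2 * 1.959963984540054)


def genotype_error_factor(h0: float, epsilon: float) -> float:
    """Multiplicative factor (H_S(0) - eps) / H_S(0) removing false hets."""
    if not 0 <= epsilon < h0:
        raise ValueError("need 0 <= epsilon < H_S(0)")
    return (h0 - epsilon) / h0


def gene_conversion_subtraction(c: float, rate_ratio: float, hbar: float,
                                h0: float) -> float:
    """Rate decrement attributable to non-crossover gene conversion.

    decrement = c * rate_ratio * (hbar - h0) / 2, subtracted from mu after
    the genotype-error factor.  A conversion tract overwrites one of the
    two donor haplotypes, hence the factor 1/2 on the heterozygosity
    excess of the genome over the (young) test regions.
    """
    if min(c, rate_ratio, hbar, h0) < 0:
        raise ValueError("inputs must be non-negative")
    if hbar <= h0:
        warnings.warn("genome-mean heterozygosity <= region heterozygosity; "
                      "gene-conversion decrement set to 0")
        return 0.0
    return c * rate_ratio * (hbar - h0) / 2.0


def estimate_genotype_error_cpg(
    n_het: np.ndarray,
    n_cpg: np.ndarray,
    h0: float,
    f_true: float,
    f_err: float,
) -> tuple[float, float]:
    """Estimate the false-heterozygote rate from CpG-transition dilution.

    ``n_het``/``n_cpg`` are per-chromosome counts of heterozygous sites
    (and the CpG transitions among them) around ascertained starting
    points.  With ``f_true`` the CpG-transition fraction among genuine
    heterozygous sites (genome-wide) and ``f_err`` the fraction expected
    among errors (defaulting upstream to the CpG-site fraction of callable
    sequence), the mixture gives

        eps = H_S(0) * (f_true - f_obs) / (f_true - f_err)

    Returns (eps, se) with the SE from a leave-one-chromosome jackknife.
    Raises when f_true <= f_err (the mixture is unidentifiable).
    """
    if f_true <= f_err:
        raise ValueError("unidentifiable: f_true must exceed f_err")
    n_het = np.asarray(n_het, dtype=float)
    n_cpg = np.asarray(n_cpg, dtype=float)
    if n_het.sum() <= 0:
        raise ValueError("no heterozygous sites supplied")

    def eps_of(idx):
        f_obs = n_cpg[idx].sum() / n_het[idx].sum()
        return h0 * (f_true - f_obs) / (f_true - f_err)

    full = eps_of(slice(None))
    g = len(n_het)
    if g < 2:
        return float(full), float("nan")
    loo = np.array([eps_of([j for j in range(g) if j != i]) for i in range(g)])
    var = (g - 1) / g * ((loo - loo.mean()) ** 2).sum()
    return float(full), float(np.sqrt(var))


def base_content_factor(region_comp: dict, genome_comp: dict,
                        params: CorrectionParams | None = None) -> float:
    """Relative-mutability rescaling from region to genome base content.

    Compositions are dicts with ``f_cpg`` (fraction of CpG sites) and
    ``f_gc`` (GC fraction), measured in 30-kb windows around starting
    points and genome-wide on filtered sites.  The mutability score is
    M(x) = 1 + b_cpg*f_cpg + b_gc*f_gc + b_int*f_cpg*f_gc and the factor
    is M(genome)/M(regions): above 1 when the regions are CpG-poorer than
    the genome.
    """
    params = params or CorrectionParams()

    def score(comp):
        f_cpg, f_gc = comp["f_cpg"], comp["f_gc"]
        if not (0 <= f_cpg <= 1 and 0 <= f_gc <= 1):
            raise ValueError("composition fractions must lie in [0, 1]")
        return (1.0 + params.beta_cpg * f_cpg + params.beta_gc * f_gc
                + params.beta_interaction * f_cpg * f_gc)

    return score(genome_comp) / score(region_comp)


@dataclass
class ClassModeSettings:
    """Class-specific settings for CpG / non-CpG partitioned estimates."""

    name: str
    s_range: tuple
    mu_grid: tuple
    half_rule: bool
    epsilon_fraction: float       # share of the full-data error rate
    gene_conversion_share: float  # share of the full gene-conversion correction
    translate_intercept: bool = False


CPG_SETTINGS = ClassModeSettings(
    name="cpg", s_range=(0.1, 2.0), mu_grid=(0.2e-8, 0.4e-8, 0.8e-8),
    half_rule=False, epsilon_fraction=float("nan"), gene_conversion_share=0.09,
    translate_intercept=True)
NONCPG_SETTINGS = ClassModeSettings(
    name="non_cpg", s_range=(4.375, 8.75), mu_grid=(1e-8, 2e-8, 4e-8),
    half_rule=True, epsilon_fraction=float("nan"), gene_conversion_share=0.91)


def class_partition(profiles, reference: dict[str, str]):
    """Split each profile's heterozygous sites into CpG-transition and other.

    ``reference`` maps chromosome name to reference sequence; profiles
    must carry allele-context flags (``het_is_cpg``) populated at read
    time, or the reference is consulted here only for the site fraction.
    Returns ``(cpg_profiles, other_profiles, settings)`` where the two
    derived profile sets keep every masked/callable field (all sites not
    in the class are treated as homozygous, putting the class rates on an
    equal denominator) and ``settings`` holds the class-mode parameters:
    ascertainment ranges S = 0.1-2 (CpG; exactly one site per window
    after filtering, half-rule off) and 4.375-8.75 (non-CpG), the reduced
    CpG calibration grid, epsilon scaled by the class site fraction, and
    the GC-bias-adjusted gene-conversion split (0.09 / 0.91).
    """
    from .genomic_io import HetProfile

    if reference is None:
        raise ValueError("class mode requires a reference sequence")
    cpg_profiles, other_profiles = [], []
    n_sites_total = 0
    n_cpg_sites = 0
    for chrom, seq in reference.items():
        s = seq.upper()
        n_sites_total += len(s)
        n_cpg_sites += 2 * s.count("CG")  # both strands of the dinucleotide
    for prof in profiles:
        if prof.het_is_cpg is None:
            raise ValueError(f"{prof.sample_id}: profile lacks CpG flags; "
                             "re-read with a reference")
        cpg_pos, other_pos = {}, {}
        for chrom, het in prof.het_positions.items():
            flags = prof.het_is_cpg.get(chrom, np.zeros(len(het), dtype=bool))
            cpg_pos[chrom] = het[flags]
            other_pos[chrom] = het[~flags]
        cpg_profiles.append(HetProfile(
            prof.sample_id + ":cpg", cpg_pos,
            {c: m.copy() for c, m in prof.mask.items()},
            dict(prof.callable_count), dict(prof.chrom_lengths)))
        other_profiles.append(HetProfile(
            prof.sample_id + ":non_cpg", other_pos,
            {c: m.copy() for c, m in prof.mask.items()},
            dict(prof.callable_count), dict(prof.chrom_lengths)))
    f_cpg_sites = n_cpg_sites / max(n_sites_total, 1)
    import dataclasses
    cpg = dataclasses.replace(CPG_SETTINGS, epsilon_fraction=f_cpg_sites)
    other = dataclasses.replace(NONCPG_SETTINGS, epsilon_fraction=1 - f_cpg_sites)
    return cpg_profiles, other_profiles, {"cpg": cpg, "non_cpg": other}
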