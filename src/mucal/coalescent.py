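"""Coalescent simulation of diploid segments for calibration and test data.

Simulation is done with msprime's Hudson algorithm, which realizes the
full ancestral recombination graph.  This matters here: the sequence of
TMRCAs along a chromosome is not Markovian (distant lineages interact in
the ARG), and the relaxation statistic the package fits is sensitive to
exactly those long-range dependencies, so an SMC-class approximation is
not acceptable for generating calibration data.

Demographic histories are piecewise-constant population sizes.  Only the
scaled diversity theta = 4*N*mu and the size history in coalescent time
are identifiable from data (e.g. from PSMC output), so calibration runs
at a chosen mutation rate ``mu_sim`` rescale the baseline size to
``N_sim = theta/(4*mu_sim)`` and epoch times proportionally.  This sets
the scaled recombination rate to rho = theta*r/mu_sim, keeping both the
diversity and the r/mu ratio appropriate for that calibration curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import msprime
import numpy as np

from .genomic_io import HetProfile
from .map_model import GeneticMap, MapErrorModel, PerturbedMap, perturb, synthetic_map

__all__ = [
    "Demography",
    "SimConfig",
    "ScenarioData",
    "simulate_super_region",
    "simulate_segment",
    "expected_block_length",
    "inject_genotype_errors",
    "scenario_genomes",
    "parse_psmc",
    "arg_block_table",
    "SCENARIOS",
]


@dataclass
class Demography:
    """Scaled diversity plus a piecewise-constant size history.

    epochs are (start time in generations, relative size lambda) with
    respect to the baseline size ``n_baseline``; time 0 (the present) at
    relative size 1 is implicit.  ``theta = 4 * n_baseline * mu`` for the
    mutation rate of the data the history was estimated from.
    """

    theta: float
    n_baseline: float
    epochs: list[tuple[float, float]] = field(default_factory=list)
    source: str = "native"

    def __post_init__(self):
        if self.theta <= 0 or self.n_baseline <= 0:
            raise ValueError("theta and baseline size must be > 0")
        times = [t for t, _ in self.epochs]
        if times != sorted(times):
            raise ValueError("epochs must be time-ordered")
        if any(lam <= 0 for _, lam in self.epochs):
            raise ValueError("relative sizes must be > 0")

    def scaled_n(self, mu_sim: float) -> float:
        return self.theta / (4.0 * mu_sim)

    def to_msprime(self, mu_sim: float) -> msprime.Demography:
        """Build the msprime demography for a run at mutation rate ``mu_sim``.

        Sizes and epoch times are rescaled by N_sim/N so the history in
        coalescent units is preserved (all that is identifiable from data).
        """
        n_sim = self.scaled_n(mu_sim)
        scale = n_sim / self.n_baseline
        dem = msprime.Demography()
        dem.add_population(name="pop", initial_size=n_sim)
        for t, lam in self.epochs:
            dem.add_population_parameters_change(
                time=t * scale, initial_size=lam * n_sim, population="pop")
        return dem


def parse_psmc(path_or_buf, mu: float, bin_size: int = 100) -> Demography:
    """Read a PSMC output file into a Demography.

    Uses the final round's TR (theta, rho per bin) and RS (k, t_k,
    lambda_k, ...) lines.  PSMC reports theta per ``bin_size``-base bin
    and times scaled by 2*N0; ``mu`` (the calibration mutation rate) is
    used to convert to generations via N0 = theta_site/(4*mu).  The reader
    is tolerant of surrounding lines (comments, other record types).
    """
    buf = open(path_or_buf) if isinstance(path_or_buf, str) else path_or_buf
    try:
        rounds: list[dict] = []
        cur: dict | None = None
        for line in buf:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "RD":
                cur = {"theta": None, "rs": []}
                rounds.append(cur)
            elif parts[0] == "TR" and cur is not None:
                cur["theta"] = float(parts[1])
            elif parts[0] == "RS" and cur is not None:
                cur["rs"].append((float(parts[2]), float(parts[3])))
    finally:
        if isinstance(path_or_buf, str):
            buf.close()
    rounds = [r for r in rounds if r["theta"] is not None and r["rs"]]
    if not rounds:
        raise ValueError("no usable TR/RS rounds found in PSMC output")
    final = rounds[-1]
    theta_site = final["theta"] / bin_size
    n0 = theta_site / (4.0 * mu)
    lam0 = final["rs"][0][1]
    epochs = [(t * 2.0 * n0, lam / lam0) for t, lam in final["rs"] if t > 0]
    return Demography(theta=theta_site, n_baseline=n0 * lam0, epochs=epochs,
                      source="psmc")


@dataclass
class SimConfig:
    """Parameters for one simulation run."""

    mu_sim: float
    gmap: GeneticMap | None = None  # map supplying per-interval rates
    n_genomes: int = 1
    seed: int | None = None
    gene_conversion_per_base: float = 0.0  # probability a base lies in a tract
    gene_conversion_tract: float = 100.0
    genotype_error_rate: float = 0.0

    def __post_init__(self):
        if self.mu_sim <= 0:
            raise ValueError("mu_sim must be > 0")
        if min(self.gene_conversion_per_base, self.genotype_error_rate) < 0:
            raise ValueError("rates must be >= 0")


def _rate_map_slice(gmap: GeneticMap, chrom: str, start: int, end: int) -> msprime.RateMap:
    """Per-base recombination rates over [start, end), relative coordinates."""
    pos, cm = gmap.grids[chrom]
    i = np.searchsorted(pos, start, side="right") - 1
    j = np.searchsorted(pos, end, side="left")
    p = pos[i:j + 1].astype(float).copy()
    c = cm[i:j + 1].copy()
    rates = np.diff(c) / 100.0 / np.diff(p)  # Morgans per base
    p[0], p[-1] = start, end
    return msprime.RateMap(position=p - start, rate=rates)


def _het_positions(ts, n_dip: int) -> list[np.ndarray]:
    """0-based integer positions heterozygous in each diploid (pairs of haplotypes)."""
    if ts.num_sites == 0:
        return [np.empty(0, dtype=np.int64) for _ in range(n_dip)]
    G = ts.genotype_matrix()
    pos = ts.tables.sites.position.astype(np.int64)
    out = []
    for k in range(n_dip):
        het = G[:, 2 * k] != G[:, 2 * k + 1]
        out.append(np.unique(pos[het]))
    return out


def simulate_segment(
    length: float,
    demography: Demography | msprime.Demography,
    config: SimConfig,
    *,
    chrom: str | None = None,
    offset: int = 0,
    rng: np.random.Generator | None = None,
    mutation_rate_map: msprime.RateMap | None = None,
    return_ts: bool = False,
):
    """Simulate ``config.n_genomes`` diploid genomes over a segment.

    Recombination rates come from ``config.gmap`` sliced at
    ``[offset, offset+length)`` on ``chrom`` (uniform 1.25e-8 if absent).
    Returns a list of per-diploid heterozygous position arrays in segment
    coordinates (and the tree sequence when requested).
    """
    rng = rng or np.random.default_rng(config.seed)
    if isinstance(demography, Demography):
        dem = demography.to_msprime(config.mu_sim)
    else:
        dem = demography
    if config.gmap is not None:
        if chrom is None:
            chrom = config.gmap.chromosomes[0]
        recomb = _rate_map_slice(config.gmap, chrom, offset, offset + int(length))
    else:
        recomb = 1.25e-8
    gc_kwargs = {}
    if config.gene_conversion_per_base > 0:
        # gene_conversion_per_base is the probability that a base lies in a
        # non-crossover tract per *diploid* generation (the convention of the
        # published rate and of the downstream correction); msprime applies
        # its initiation rate per lineage, i.e. per meiosis, hence the 1/2.
        init_rate = config.gene_conversion_per_base / (2.0 * config.gene_conversion_tract)
        gc_kwargs = dict(
            gene_conversion_rate=init_rate,
            gene_conversion_tract_length=config.gene_conversion_tract,
        )
    if dem.num_populations > 1:
        samples = {dem.populations[0].name: config.n_genomes}
    else:
        samples = config.n_genomes
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=int(length) if config.gmap is None else None,
        recombination_rate=recomb,
        random_seed=int(rng.integers(1, 2**31)),
        **gc_kwargs,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=mutation_rate_map if mutation_rate_map is not None else config.mu_sim,
        random_seed=int(rng.integers(1, 2**31)),
        model=msprime.BinaryMutationModel(),
    )
    hets = _het_positions(ts, config.n_genomes)
    return (hets, ts) if return_ts else hets


def simulate_super_region(region, demography, config: SimConfig,
                          rng: np.random.Generator | None = None,
                          return_ts: bool = False):
    """Simulate diploid data over one super-region (absolute coordinates).

    Heterozygous positions are returned in chromosome coordinates.
    Raises for regions of zero genetic length on the supplied map.
    """
    if config.gmap is not None:
        span_cm = float(np.diff(config.gmap.interpolate(
            region.chrom, [region.start, region.end]))[0])
        if span_cm <= 0:
            raise ValueError(f"super-region {region.chrom}:{region.start}-{region.end} "
                             "has zero genetic length")
    res = simulate_segment(
        region.length, demography, config,
        chrom=region.chrom, offset=region.start, rng=rng, return_ts=return_ts)
    hets = res[0] if return_ts else res
    hets = [h + region.start for h in hets]
    return (hets, res[1]) if return_ts else hets


def expected_block_length(T: float, r: float) -> float:
    """Expected length (bases) of a non-recombined block of TMRCA ``T``:
    1/(2*T*r)."""
    if T <= 0 or r <= 0:
        raise ValueError("T and r must be > 0")
    return 1.0 / (2.0 * T * r)


def arg_block_table(length: float, r: float, mu: float, demography,
                    seed: int = 1) -> "pd.DataFrame":
    """Simulate one diploid with the full ARG recorded and tabulate blocks.

    Blocks are the intervals between recorded ancestral recombination
    breakpoints; each row carries the block span, TMRCA, and the number of
    heterozygous sites.  The expected number of het sites per block,
    regardless of age, is mu/r.
    """
    import pandas as pd

    dem = demography.to_msprime(mu) if isinstance(demography, Demography) else demography
    ts = msprime.sim_ancestry(
        samples=1, demography=dem, sequence_length=int(length),
        recombination_rate=r, record_full_arg=True, random_seed=seed)
    ts = msprime.sim_mutations(ts, rate=mu, random_seed=seed + 1,
                               model=msprime.BinaryMutationModel())
    het_pos = np.sort(_het_positions(ts, 1)[0]).astype(float)
    rows = []
    for tree in ts.trees():
        left, right = tree.interval
        mrca = tree.mrca(0, 1)
        n_het = int(np.searchsorted(het_pos, right) - np.searchsorted(het_pos, left))
        rows.append((left, right, right - left, tree.time(mrca), n_het))
    return pd.DataFrame(rows, columns=["left", "right", "span", "tmrca", "n_het"])


def inject_genotype_errors(profile: HetProfile, rate: float,
                           rng: np.random.Generator) -> tuple[HetProfile, dict]:
    """Add false heterozygous sites uniformly at unmasked homozygous positions.

    The number per chromosome is Poisson with mean rate * callable sites.
    Returns a new profile plus the injected positions per chromosome, so
    simulation-study runs can count errors in ascertained regions directly.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    from . import intervals as iv

    new_het, injected = {}, {}
    for chrom, het in profile.het_positions.items():
        length = profile.chrom_lengths[chrom]
        n_call = profile.callable_count.get(chrom, length)
        n_err = rng.poisson(rate * n_call) if rate > 0 else 0
        taken = set(het.tolist())
        mask = profile.mask.get(chrom, np.empty((0, 2), dtype=np.int64))
        pts: list[int] = []
        while len(pts) < n_err:
            cand = rng.integers(0, length, size=max(n_err - len(pts), 1))
            cand = cand[~iv.contains(mask, cand)]
            for c in cand.tolist():
                if c not in taken:
                    taken.add(c)
                    pts.append(c)
                if len(pts) == n_err:
                    break
        inj = np.sort(np.asarray(pts, dtype=np.int64))
        injected[chrom] = inj
        new_het[chrom] = np.union1d(het, inj)
    prof = HetProfile(profile.sample_id, new_het,
                      {c: m.copy() for c, m in profile.mask.items()},
                      dict(profile.callable_count), dict(profile.chrom_lengths))
    return prof, injected


# ---------------------------------------------------------------------------
# Scenario generator for the simulation study
# ---------------------------------------------------------------------------

SCENARIOS = ("baseline", "low_mu", "gene_conversion", "genotype_error",
             "variable_mu", "admixture", "combined")

#: Study conditions: true rate 2.5e-8 with ancestral size 10,000 (or
#: 1.5e-8 with 16,666, preserving theta = 1e-3), a 10x bottleneck from
#: 1000 to 2000 generations ago, and a perturbed map with alpha = 3000
#: per Morgan and pseudo-count prior 0.09 cM/Mb.
BASE_N = 10_000
BASE_MU = 2.5e-8
LOW_MU = 1.5e-8
LOW_MU_N = 16_666
BOTTLENECK = [(1000.0, 0.1), (2000.0, 1.0)]
GENE_CONVERSION_PER_BASE = 5.9e-6
GENE_CONVERSION_TRACT = 100.0
ERROR_RATE = 1e-5          # 1 false het per 100 kb
ERROR_RATE_COMBINED = 1.0 / 150_000.0
SIM_ALPHA = 3000.0
VARIABLE_MU_CV = 0.3       # window-level lognormal rate multipliers
ADMIX_SPLIT_GEN = 3000.0
ADMIX_TIME_GEN = 100.0
ADMIX_FRACTION = 0.5


@dataclass
class ScenarioData:
    """A full synthetic input set plus the ground truth used to create it."""

    scenario: str
    profiles: list[HetProfile]
    base_map: GeneticMap
    true_map: PerturbedMap | GeneticMap
    demography: Demography
    truth: dict
    injected_errors: dict  # sample -> chrom -> positions

    def save(self, out_dir: str) -> None:
        """Write the data set as plain-text files (maps and profiles as TSV,
        truth and demography as JSON)."""
        import json
        import os

        os.makedirs(out_dir, exist_ok=True)
        self.base_map.to_tsv(os.path.join(out_dir, "base_map.tsv"))
        self.true_map.to_tsv(os.path.join(out_dir, "true_map.tsv"))
        for prof in self.profiles:
            prof.to_tsv(os.path.join(out_dir, f"profile_{prof.sample_id}.tsv"))
        record = {
            "scenario": self.scenario,
            "truth": self.truth,
            "samples": [p.sample_id for p in self.profiles],
            "chrom_lengths": self.profiles[0].chrom_lengths,
            "demography": {
                "theta": self.demography.theta,
                "n_baseline": self.demography.n_baseline,
                "epochs": self.demography.epochs,
            },
            "injected_errors": {
                s: {c: np.asarray(p).tolist() for c, p in d.items()}
                for s, d in self.injected_errors.items()
            },
        }
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(record, fh, indent=1)

    @classmethod
    def load(cls, out_dir: str) -> "ScenarioData":
        import json
        import os

        import pandas as pd

        with open(os.path.join(out_dir, "truth.json")) as fh:
            record = json.load(fh)
        chrom_lengths = {c: int(l) for c, l in record["chrom_lengths"].items()}
        profiles = []
        for sample in record["samples"]:
            df = pd.read_csv(os.path.join(out_dir, f"profile_{sample}.tsv"), sep="\t")
            het = {c: np.sort(g["pos"].to_numpy(dtype=np.int64))
                   for c, g in df.groupby("chrom")}
            for c in chrom_lengths:
                het.setdefault(c, np.empty(0, dtype=np.int64))
            profiles.append(HetProfile(sample, het, {}, dict(chrom_lengths),
                                       dict(chrom_lengths)))
        dem = record["demography"]
        return cls(
            scenario=record["scenario"],
            profiles=profiles,
            base_map=GeneticMap.from_tsv(os.path.join(out_dir, "base_map.tsv")),
            true_map=GeneticMap.from_tsv(os.path.join(out_dir, "true_map.tsv")),
            demography=Demography(theta=dem["theta"], n_baseline=dem["n_baseline"],
                                  epochs=[tuple(e) for e in dem["epochs"]]),
            truth=record["truth"],
            injected_errors={
                s: {c: np.asarray(p, dtype=np.int64) for c, p in d.items()}
                for s, d in record["injected_errors"].items()
            },
        )


def _admixture_demography(n: float, mu_ratio_scale: float = 1.0) -> msprime.Demography:
    dem = msprime.Demography()
    dem.add_population(name="ADMIX", initial_size=n)
    dem.add_population(name="A", initial_size=n)
    dem.add_population(name="B", initial_size=n)
    dem.add_population(name="ANC", initial_size=n)
    dem.add_admixture(time=ADMIX_TIME_GEN, derived="ADMIX", ancestral=["A", "B"],
                      proportions=[ADMIX_FRACTION, 1 - ADMIX_FRACTION])
    for pop in ("A", "B"):
        dem.add_population_parameters_change(time=1000, initial_size=n / 10, population=pop)
        dem.add_population_parameters_change(time=2000, initial_size=n, population=pop)
    dem.add_population_split(time=ADMIX_SPLIT_GEN, derived=["A", "B"], ancestral="ANC")
    dem.sort_events()
    return dem


def scenario_genomes(
    scenario: str,
    seed: int,
    n_genomes: int = 20,
    n_chrom: int = 22,
    chrom_length: int = 5_000_000,
) -> ScenarioData:
    """Generate test genomes and truth record for one study scenario.

    The genomes are simulated segment-per-chromosome under a synthetic
    heterogeneous base map perturbed once (the data's "true" map, drawn
    with alpha = 3000 M^-1, pi = 0.09 cM/Mb); downstream analysis only
    ever sees the base map, mirroring the real-data situation where the
    published map differs from the truth.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    rng = np.random.default_rng(seed)
    mu = LOW_MU if scenario in ("low_mu", "gene_conversion") else BASE_MU
    n_base = LOW_MU_N if scenario in ("low_mu", "gene_conversion") else BASE_N
    theta = 4.0 * n_base * mu
    demog = Demography(theta=theta, n_baseline=n_base, epochs=list(BOTTLENECK))

    chrom_lengths = {f"chr{i+1}": chrom_length for i in range(n_chrom)}
    base_map = synthetic_map(chrom_lengths, seed=int(rng.integers(2**31)))
    err_model = MapErrorModel(alpha=SIM_ALPHA)
    true_map = perturb(base_map, err_model, rng)

    gc_rate = GENE_CONVERSION_PER_BASE if scenario == "gene_conversion" else 0.0
    use_admix = scenario in ("admixture", "combined")
    use_varmu = scenario in ("variable_mu", "combined")
    err_rate = (ERROR_RATE if scenario == "genotype_error"
                else ERROR_RATE_COMBINED if scenario == "combined" else 0.0)

    cfg = SimConfig(mu_sim=mu, gmap=true_map, n_genomes=n_genomes,
                    gene_conversion_per_base=gc_rate,
                    gene_conversion_tract=GENE_CONVERSION_TRACT)

    hets_by_sample: list[dict[str, np.ndarray]] = [dict() for _ in range(n_genomes)]
    mu_multipliers: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        dem = (_admixture_demography(demog.scaled_n(mu)) if use_admix
               else demog.to_msprime(mu))
        rate_map = None
        if use_varmu:
            sigma = float(np.sqrt(np.log(1 + VARIABLE_MU_CV**2)))
            n_win = max(length // 100_000, 1)
            mult = rng.lognormal(-sigma**2 / 2, sigma, size=n_win)
            mu_multipliers[chrom] = mult
            edges = np.linspace(0, length, n_win + 1)
            rate_map = msprime.RateMap(position=edges, rate=mu * mult)
        hets = simulate_segment(length, dem, cfg, chrom=chrom, offset=0,
                                rng=rng, mutation_rate_map=rate_map)
        for k in range(n_genomes):
            hets_by_sample[k][chrom] = hets[k]

    profiles = [
        HetProfile(f"sim{k}", hets_by_sample[k], {},
                   {c: l for c, l in chrom_lengths.items()},
                   dict(chrom_lengths))
        for k in range(n_genomes)
    ]
    injected: dict[str, dict] = {}
    if err_rate > 0:
        new_profiles = []
        for prof in profiles:
            prof2, inj = inject_genotype_errors(prof, err_rate, rng)
            new_profiles.append(prof2)
            injected[prof.sample_id] = inj
        profiles = new_profiles

    truth = {
        "scenario": scenario, "mu_true": mu, "theta": theta, "n_baseline": n_base,
        "epochs": list(BOTTLENECK), "gene_conversion_per_base": gc_rate,
        "gene_conversion_tract": GENE_CONVERSION_TRACT if gc_rate else None,
        "genotype_error_rate": err_rate, "alpha": SIM_ALPHA,
        "admixture": use_admix, "variable_mu": use_varmu,
        "n_genomes": n_genomes, "n_chrom": n_chrom, "chrom_length": chrom_length,
        "seed": seed,
    }
    return ScenarioData(scenario, profiles, base_map, true_map, demog, truth, injected)
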