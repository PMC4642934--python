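"""End-to-end orchestration of the simulation study and single-dataset runs.

A trial runs the complete pipeline on one synthetic data set: simulate
test genomes, tile and ascertain starting points, compute the observed
H_S(d) curve, build matched calibration curves by coalescent simulation
under a freshly perturbed map at a grid of mutation rates, fit mu by
variance-weighted least squares, apply the applicable corrections, and
attach a leave-one-chromosome jackknife standard error.  A scenario run
repeats trials with independent seeds and summarizes recovery (mean and
SD of the estimates, mean jackknife SE) so that realized spread and the
jackknife can be compared.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ascertainment import (WINDOW_SIZE, ascertain, define_super_regions,
                            tile_and_count)
from .coalescent import (Demography, ScenarioData, SimConfig, scenario_genomes,
                         simulate_super_region, SCENARIOS)
from .corrections import (CorrectionParams, gene_conversion_subtraction,
                          genotype_error_factor)
from .estimator import (CalibrationSet, DEFAULT_MU_GRID, RateEstimate,
                        average_calibrations, fit_mu, smooth_variances,
                        weighted_jackknife)
from .hs import CurveValues, HSCurve, asymptote_adjust, compute_curve, region_geometry
from .map_model import GeneticMap, MapErrorModel, perturb

__all__ = ["ScaleProfile", "TrialResult", "run_trial", "run_scenario",
            "scale_profile", "build_calibration_curves", "local_rate_ratio"]


@dataclass
class ScaleProfile:
    """Problem sizes for a study run.

    ``full`` mirrors the validation-study conditions (20 genomes, 25 trials, 30
    simulated genomes per calibration curve); ``desk`` is a reduced
    profile (4 genomes, 5 trials) sized to complete on a single CPU in
    minutes while leaving enough starting points (a few hundred) for the
    weighted fit to be stable.
    """

    name: str
    n_genomes: int
    n_trials: int
    n_chrom: int
    chrom_length: int
    calib_genomes: int            # simulated genomes per curve and super-region
    calib_region_cap: int | None  # subsample of super-regions used per curve
    n_calibrations: int = 1       # independent calibrations averaged per trial
    mu_grid: tuple = DEFAULT_MU_GRID
    s_range: tuple = (5, 10)
    alpha: float = 3000.0
    pi_cm_per_mb: float = 0.09


_PROFILES = {
    "full": ScaleProfile("full", n_genomes=20, n_trials=25, n_chrom=22,
                          chrom_length=5_000_000, calib_genomes=30,
                          calib_region_cap=None),
    "desk": ScaleProfile("desk", n_genomes=4, n_trials=5, n_chrom=16,
                         chrom_length=4_000_000, calib_genomes=10,
                         calib_region_cap=140, n_calibrations=2),
}


def scale_profile(name: str) -> ScaleProfile:
    try:
        import dataclasses
        return dataclasses.replace(_PROFILES[name])
    except KeyError:
        raise ValueError(f"unknown scale profile {name!r}") from None


@dataclass
class TrialResult:
    scenario: str
    seed: int
    mu_true: float
    mu_raw: float
    mu_corrected: float
    jackknife_se: float
    n_points: int
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mu_corrected <= 0:
            raise ValueError("corrected mu must be positive")


def _window_bounds(midpoint: int, window: int = WINDOW_SIZE) -> tuple[int, int]:
    return midpoint - window // 2, midpoint + window // 2


def _qualifies(het: np.ndarray, midpoint: int, s_range, half_rule: bool,
               window: int = WINDOW_SIZE):
    """Does a simulated genome's central window pass the ascertainment rule?"""
    lo, hi = _window_bounds(midpoint, window)
    i, j = np.searchsorted(het, [lo, hi])
    n = j - i
    if not (s_range[0] <= n <= s_range[1]):
        return None
    if half_rule:
        k = np.searchsorted(het, midpoint)
        if k - i < 1 or j - k < 1:
            return None
    return int(n)


def build_calibration_curves(
    regions,
    demography: Demography,
    base_map: GeneticMap,
    perturbed_map: GeneticMap,
    rng: np.random.Generator,
    *,
    mu_grid=DEFAULT_MU_GRID,
    n_genomes: int = 5,
    s_range=(5, 10),
    half_rule: bool = True,
    cache: dict | None = None,
) -> dict[float, HSCurve]:
    """Simulate calibration data over super-regions for each grid mu.

    Each super-region is simulated independently (full-ARG coalescent)
    under the perturbed map; genomes whose central 100-kb window passes
    the same ascertainment rule as the real data contribute to the curve,
    with all genetic distances measured on the *base* map.  For each
    ascertained genome, the region-mean heterozygosity (used by the
    asymptote adjustment) pools the *other* simulated genomes over the
    span, mirroring the owner-excluded span mean computed on the data.
    """
    curves = {mu: HSCurve() for mu in mu_grid}
    for region in regions:
        geo = region_geometry(base_map, region, cache)
        mid = region.points[0].midpoint
        for mu_c in mu_grid:
            cfg = SimConfig(mu_sim=mu_c, gmap=perturbed_map, n_genomes=n_genomes)
            hets = simulate_super_region(region, demography, cfg, rng=rng)
            curve = curves[mu_c]
            total_het = sum(len(h) for h in hets)
            for het in hets:
                n = _qualifies(het, mid, s_range, half_rule)
                if n is None:
                    continue
                others_het = total_het - len(het) if n_genomes > 1 else len(het)
                n_others = n_genomes - 1 if n_genomes > 1 else 1
                curve.add(region.chrom,
                          het=geo.bincount(het), sites=geo.site_counts,
                          h0_het=n, h0_sites=WINDOW_SIZE, n_points=1,
                          hbar_het=others_het,
                          hbar_sites=n_others * region.length)
    return curves


def local_rate_ratio(points, gmap: GeneticMap, window: int = 10_000) -> float:
    """Mean map rate in 10-kb windows at starting points over the genome mean."""
    rates = []
    for pt in points:
        lo, hi = pt.midpoint - window // 2, pt.midpoint + window // 2
        lo_map, hi_map = gmap.span(pt.chrom)
        lo, hi = max(lo, lo_map), min(hi, hi_map)
        cm = gmap.interpolate(pt.chrom, [lo, hi])
        rates.append((cm[1] - cm[0]) / ((hi - lo) / 1e6))
    return float(np.mean(rates) / gmap.mean_rate_cm_per_mb())


def _global_het(profiles, exclude: str | None = None) -> float:
    het = sites = 0
    for prof in profiles:
        for chrom in prof.het_positions:
            if chrom == exclude:
                continue
            het += len(prof.het_positions[chrom])
            sites += prof.callable_count.get(chrom, prof.chrom_lengths[chrom])
    return het / sites if sites else 0.0


def _count_errors_in_windows(data: ScenarioData, points, exclude: str | None = None):
    """Directly counted injected-error rate over ascertained windows."""
    n_err = n_sites = 0
    for pt in points:
        if pt.chrom == exclude:
            continue
        inj = data.injected_errors.get(pt.sample_id, {}).get(pt.chrom)
        if inj is None:
            continue
        lo, hi = _window_bounds(pt.midpoint)
        i, j = np.searchsorted(inj, [lo, hi])
        n_err += j - i
        n_sites += pt.n_unmasked
    return (n_err / n_sites) if n_sites else 0.0


def run_trial(
    data: ScenarioData,
    profile: ScaleProfile,
    seed: int,
    corrections: CorrectionParams | None = None,
) -> TrialResult:
    """Run the full inference pipeline on one synthetic data set."""
    rng = np.random.default_rng(seed)
    corrections = corrections or CorrectionParams()
    truth = data.truth
    apply_error = truth.get("genotype_error_rate", 0) > 0
    apply_gc = truth.get("gene_conversion_per_base", 0) > 0

    windows = tile_and_count(data.profiles)
    points = ascertain(windows, s_range=profile.s_range)
    regions = define_super_regions(points, data.base_map)
    if len({r.chrom for r in regions}) < 2:
        raise ValueError("need starting points on at least two chromosomes")

    cache: dict = {}
    obs = compute_curve(data.profiles, regions, data.base_map, cache)
    err_model = MapErrorModel(alpha=profile.alpha, pi_cm_per_mb=profile.pi_cm_per_mb)

    calib_regions = regions
    if profile.calib_region_cap and len(regions) > profile.calib_region_cap:
        idx = rng.choice(len(regions), size=profile.calib_region_cap, replace=False)
        calib_regions = [regions[i] for i in sorted(idx)]

    # Independent calibrations, each under a fresh perturbed map, pooled into
    # one curve set per trial: pooling before the fit integrates over the
    # map-perturbation randomness while keeping the family curves as smooth
    # as the budget allows (a noisy family biases the fit through the
    # convex mu-spacing).  ``average_calibrations`` of separate fits is the
    # alternative when single-calibration fits are themselves stable.
    pooled: dict[float, HSCurve] = {mu: HSCurve() for mu in profile.mu_grid}
    for rep in range(profile.n_calibrations):
        pert = perturb(data.base_map, err_model, rng)
        curves = build_calibration_curves(
            calib_regions, data.demography, data.base_map, pert, rng,
            mu_grid=profile.mu_grid, n_genomes=profile.calib_genomes,
            s_range=profile.s_range, cache=cache)
        for mu_c, c in curves.items():
            for chrom, e in c._chrom.items():
                pooled[mu_c].add(chrom, het=e["het"], sites=e["sites"],
                                 h0_het=e["h0_het"], h0_sites=e["h0_sites"],
                                 hbar_het=e["hbar_het"], hbar_sites=e["hbar_sites"],
                                 n_points=e["n_points"])
    calib_reps = [pooled]

    rate_ratio = local_rate_ratio(points, data.base_map)

    def estimate(exclude: str | None = None) -> tuple[float, float]:
        obs_vals = CurveValues(obs.h(exclude), obs.h0(exclude))
        sites = np.sum([e["sites"] for c, e in obs._chrom.items() if c != exclude], axis=0)
        fits = []
        for curves in calib_reps:
            adjusted = []
            # the simulated span-mean heterozygosity is mu-invariant under the
            # theta-preserving rescaling, so pool it across the grid curves
            hb_het = sum(curves[m]._sum("hbar_het", exclude) for m in profile.mu_grid)
            hb_sites = sum(curves[m]._sum("hbar_sites", exclude) for m in profile.mu_grid)
            hbar_sim = hb_het / hb_sites if hb_sites > 0 else obs.hbar(exclude)
            for mu_c in profile.mu_grid:
                c = curves[mu_c]
                vals = CurveValues(c.h(exclude), c.h0(exclude))
                adjusted.append(asymptote_adjust(vals, obs.hbar(exclude), hbar_sim))
            calib = CalibrationSet(tuple(profile.mu_grid), adjusted)
            variances = _variance_model(adjusted, sites)
            fits.append(fit_mu(obs_vals, calib, variances))
        mu_raw = average_calibrations(fits)
        mu_hat = mu_raw
        if apply_error:
            eps = _count_errors_in_windows(data, points, exclude)
            mu_hat *= genotype_error_factor(obs.h0(exclude), eps)
        if apply_gc:
            dec = gene_conversion_subtraction(
                truth["gene_conversion_per_base"], rate_ratio,
                _global_het(data.profiles, exclude), obs.h0(exclude))
            mu_hat -= dec
        return mu_raw, mu_hat

    mu_raw, mu_corrected = estimate()

    per_chrom = obs.points_per_chrom()
    chroms = [c for c, n in per_chrom.items() if n > 0]
    loo = np.array([estimate(exclude=c)[1] for c in chroms])
    weights = np.array([per_chrom[c] for c in chroms], dtype=float)
    jk_se = weighted_jackknife(mu_corrected, loo, weights)

    corr_ledger: dict = {}
    param_se: dict = {}
    if apply_error:
        eps = _count_errors_in_windows(data, points)
        n_err = sum(
            len(data.injected_errors.get(pt.sample_id, {}).get(pt.chrom, ()))
            for pt in points)
        corr_ledger["genotype_error_factor"] = genotype_error_factor(obs.h0(), eps)
        corr_ledger["epsilon"] = eps
        # Poisson counting error on the directly counted rate
        param_se["epsilon"] = mu_raw * (np.sqrt(max(n_err, 1)) /
                                        max(n_err, 1) * eps) / obs.h0()
    if apply_gc:
        dec = gene_conversion_subtraction(
            truth["gene_conversion_per_base"], rate_ratio,
            _global_het(data.profiles), obs.h0())
        corr_ledger["gene_conversion_decrement"] = dec
        c = truth["gene_conversion_per_base"]
        param_se["gene_conversion"] = dec * corrections.gene_conversion_se / c
    estimate_record = RateEstimate(
        mu_raw=mu_raw, mu_corrected=mu_corrected, corrections=corr_ledger,
        jackknife_se=jk_se, parameter_se=param_se)

    details = {
        "n_regions": len(regions), "n_calib_regions": len(calib_regions),
        "h0": obs.h0(), "hbar_regions": obs.hbar(),
        "hbar_global": _global_het(data.profiles),
        "rate_ratio": rate_ratio,
        "estimate": estimate_record.to_dict(),
    }
    return TrialResult(
        scenario=data.scenario, seed=seed, mu_true=truth["mu_true"],
        mu_raw=mu_raw, mu_corrected=mu_corrected, jackknife_se=jk_se,
        n_points=len(regions), details=details)


def _variance_model(adjusted_curves, sites: np.ndarray) -> np.ndarray:
    """Smooth per-bin variance profile for the weighted fit.

    Proportional to H(d)/n_sites(d) — the sampling variance of a pooled
    heterozygosity ratio — with the level H(d) taken from the calibration
    family mean smoothed over neighbouring bins.  Deriving the weights
    from the (smooth) calibration family rather than the observed curve's
    own empirical variances keeps each bin's weight independent of that
    bin's noise; empirical jackknife variances remain available via
    ``HSCurve.bin_variances`` for uncertainty reporting.
    """
    h_fam = np.mean([c.h for c in adjusted_curves], axis=0)
    half = 4
    h_smooth = np.array([h_fam[max(0, i - half):i + half + 1].mean()
                         for i in range(len(h_fam))])
    h_smooth = np.maximum(h_smooth, 1e-12)
    return h_smooth / np.maximum(sites, 1.0)


def _bin_variances(curve: HSCurve, exclude: str | None) -> np.ndarray:
    if exclude is None:
        return curve.bin_variances()
    chroms = [c for c in curve.chromosomes if c != exclude]
    g = len(chroms)
    if g < 2:
        return curve.bin_variances()
    loo = np.array([_h_excluding(curve, {c, exclude}) for c in chroms])
    mean = loo.mean(axis=0)
    return (g - 1) / g * ((loo - mean) ** 2).sum(axis=0)


def _h_excluding(curve: HSCurve, excluded: set) -> np.ndarray:
    het = np.sum([e["het"] for c, e in curve._chrom.items() if c not in excluded], axis=0)
    sites = np.sum([e["sites"] for c, e in curve._chrom.items() if c not in excluded], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sites > 0, het / np.maximum(sites, 1), 0.0)


def run_scenario(
    scenario: str,
    n_trials: int | None = None,
    profile: ScaleProfile | str = "desk",
    seed: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Run repeated independent trials of a study scenario.

    Returns (per-trial table, summary).  The summary compares the
    realized SD of the corrected estimates across trials with the mean
    jackknife SE, the check used to validate the error model.  Failed
    trials (e.g. ascertainment finding no eligible windows) are recorded
    and excluded from the summary, never silently dropped.
    """
    if isinstance(profile, str):
        profile = scale_profile(profile)
    n_trials = n_trials or profile.n_trials
    rows, failures = [], []
    import zlib
    ss = np.random.SeedSequence([seed, zlib.crc32(scenario.encode()) % (2**31)])
    trial_seeds = ss.generate_state(2 * n_trials).reshape(n_trials, 2) % (2**31 - 1) + 1
    for t in range(n_trials):
        t0 = time.time()
        try:
            data = scenario_genomes(
                scenario, seed=int(trial_seeds[t, 0]),
                n_genomes=profile.n_genomes, n_chrom=profile.n_chrom,
                chrom_length=profile.chrom_length)
            res = run_trial(data, profile, seed=int(trial_seeds[t, 1]))
            row = asdict(res)
            row.pop("details")
            row["runtime_s"] = time.time() - t0
            rows.append(row)
        except ValueError as err:
            failures.append({"trial": t, "error": str(err)})
            warnings.warn(f"{scenario} trial {t} failed: {err}")
    table = pd.DataFrame(rows)
    summary = {
        "scenario": scenario, "profile": profile.name, "n_trials": n_trials,
        "n_failed": len(failures), "failures": failures,
    }
    if len(table):
        summary.update({
            "mu_true": float(table["mu_true"].iloc[0]),
            "mean_mu_raw": float(table["mu_raw"].mean()),
            "mean_mu_corrected": float(table["mu_corrected"].mean()),
            "sd_mu_corrected": float(table["mu_corrected"].std(ddof=1)) if len(table) > 1 else float("nan"),
            "mean_jackknife_se": float(table["jackknife_se"].mean()),
            "se_of_mean": (float(table["mu_corrected"].std(ddof=1) / np.sqrt(len(table)))
                           if len(table) > 1 else float("nan")),
        })
    return table, summary
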