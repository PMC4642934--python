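import io

import numpy as np
import pytest

from mucal.coalescent import (Demography, SimConfig, arg_block_table,
                              expected_block_length, inject_genotype_errors,
                              parse_psmc, scenario_genomes, simulate_segment,
                              simulate_super_region)
from mucal.genomic_io import HetProfile


@pytest.fixture(scope="module")
def flat_demography():
    return Demography(theta=1e-3, n_baseline=10_000)


class TestDemographyScaling:
    def test_rho_equals_theta_r_over_mu(self, flat_demography):
        # N = 10,000 and mu = 2.5e-8 give theta = 1e-3; with r = 1.25e-8
        # the scaled recombination rate must be theta*r/mu = 5e-4 per base
        r = 1.25e-8
        for mu_sim in (1e-8, 2.5e-8, 4e-8):
            n_sim = flat_demography.scaled_n(mu_sim)
            rho = 4 * n_sim * r
            assert rho == pytest.approx(flat_demography.theta * r / mu_sim)
        assert flat_demography.scaled_n(2.5e-8) == pytest.approx(10_000)

    def test_epoch_times_rescale_with_population_size(self):
        dem = Demography(theta=1e-3, n_baseline=10_000,
                         epochs=[(1000.0, 0.1), (2000.0, 1.0)])
        msp = dem.to_msprime(1e-8)  # N doubles to 25,000
        times = [e.time for e in msp.events]
        assert times == pytest.approx([2500.0, 5000.0])

    def test_invalid_histories_rejected(self):
        with pytest.raises(ValueError):
            Demography(theta=1e-3, n_baseline=1e4, epochs=[(2000, 1.0), (1000, 0.1)])
        with pytest.raises(ValueError):
            Demography(theta=-1e-3, n_baseline=1e4)

    def test_constant_population_heterozygosity_matches_theta(self, flat_demography):
        # E[het] = theta for a constant-size population; Monte-Carlo check
        cfg = SimConfig(mu_sim=2.5e-8, n_genomes=2)
        hets = []
        rng = np.random.default_rng(5)
        L = 400_000
        for _ in range(30):
            out = simulate_segment(L, flat_demography, cfg, rng=rng)
            hets.extend(len(h) / L for h in out)
        mean = np.mean(hets)
        se = np.std(hets, ddof=1) / np.sqrt(len(hets))
        assert mean == pytest.approx(1e-3, abs=3 * se)


class TestBlocks:
    def test_expected_block_length_closed_form(self):
        assert expected_block_length(2000, 1.25e-8) == pytest.approx(20_000)
        assert expected_block_length(4000, 1.25e-8) == pytest.approx(10_000)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            expected_block_length(0, 1e-8)

    @pytest.fixture(scope="class")
    def block_table(self, flat_demography):
        # mu/r = 2; ~1e4 blocks need ~20 Mb at breakpoint density 2*E[T]*r
        return arg_block_table(2e7, r=1.25e-8, mu=2.5e-8,
                               demography=flat_demography, seed=17)

    def test_mean_het_sites_per_block_is_mu_over_r(self, block_table):
        assert len(block_table) >= 5_000
        got = block_table["n_het"].sum() / len(block_table)
        assert got == pytest.approx(2.0, rel=0.10)

    def test_block_lengths_conditioned_on_tmrca(self, block_table):
        t_med = block_table["tmrca"].median()
        sel = block_table[(block_table["tmrca"] > 0.9 * t_med)
                          & (block_table["tmrca"] < 1.1 * t_med)]
        expected = expected_block_length(t_med, 1.25e-8)
        assert sel["span"].mean() == pytest.approx(expected, rel=0.15)


class TestErrorInjection:
    def _profile(self, rng, length=2_000_000, n_het=400):
        het = np.sort(rng.choice(length, size=n_het, replace=False))
        return HetProfile("g", {"chr1": het}, {}, {"chr1": length}, {"chr1": length})

    def test_zero_rate_unchanged(self, rng):
        prof = self._profile(rng)
        out, injected = inject_genotype_errors(prof, 0.0, rng)
        assert np.array_equal(out.het_positions["chr1"], prof.het_positions["chr1"])
        assert len(injected["chr1"]) == 0

    def test_poisson_count_and_no_collisions(self, rng):
        prof = self._profile(rng)
        out, injected = inject_genotype_errors(prof, 1e-4, rng)
        n = len(injected["chr1"])
        lam = 1e-4 * 2_000_000
        assert abs(n - lam) < 5 * np.sqrt(lam)
        assert len(np.intersect1d(injected["chr1"], prof.het_positions["chr1"])) == 0
        assert len(out.het_positions["chr1"]) == len(prof.het_positions["chr1"]) + n

    def test_injection_respects_mask(self, rng):
        het = np.array([500_000])
        mask = np.array([[0, 400_000]])
        prof = HetProfile("g", {"chr1": het}, {"chr1": mask},
                          {"chr1": 600_000}, {"chr1": 1_000_000})
        out, injected = inject_genotype_errors(prof, 5e-4, rng)
        assert len(injected["chr1"]) > 0
        assert injected["chr1"].min() >= 400_000


class TestPsmcParsing:
    PSMC_TEXT = "\n".join([
        "CC\tcomment",
        "RD\t0",
        "TR\t0.02\t0.003",
        "RS\t0\t0.0\t1.0\t0\t0",
        "RS\t1\t0.2\t0.5\t0\t0",
        "//",
        "RD\t20",
        "TR\t0.0300\t0.0040",
        "RS\t0\t0.000\t1.000\t0\t0",
        "RS\t1\t0.050\t0.200\t0\t0",
        "RS\t2\t0.200\t2.500\t0\t0",
        "//",
    ]) + "\n"

    def test_final_round_parsed_and_rescaled(self):
        mu = 2.5e-8
        dem = parse_psmc(io.StringIO(self.PSMC_TEXT), mu=mu, bin_size=100)
        theta_site = 0.03 / 100
        n0 = theta_site / (4 * mu)
        assert dem.theta == pytest.approx(theta_site)
        assert dem.n_baseline == pytest.approx(n0)
        # times scaled by 2*N0, sizes relative to the first epoch
        assert dem.epochs[0][0] == pytest.approx(0.05 * 2 * n0)
        assert dem.epochs[0][1] == pytest.approx(0.2)
        assert dem.epochs[1][1] == pytest.approx(2.5)
        assert dem.source == "psmc"

    def test_no_rounds_is_error(self):
        with pytest.raises(ValueError):
            parse_psmc(io.StringIO("CC nothing here\n"), mu=2.5e-8)


class TestScenarios:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario_genomes("nope", seed=1)

    def test_baseline_study_conditions(self, baseline_data):
        t = baseline_data.truth
        assert t["mu_true"] == 2.5e-8
        assert t["n_baseline"] == 10_000
        assert t["epochs"] == [(1000.0, 0.1), (2000.0, 1.0)]
        assert t["alpha"] == 3000.0
        assert len(baseline_data.profiles) == 3
        assert not baseline_data.injected_errors

    def test_low_mu_preserves_theta(self):
        data = scenario_genomes("low_mu", seed=3, n_genomes=2, n_chrom=2,
                                chrom_length=500_000)
        assert data.truth["mu_true"] == 1.5e-8
        assert data.truth["theta"] == pytest.approx(1e-3, rel=1e-3)

    def test_genotype_error_scenario_injects_recorded_errors(self):
        data = scenario_genomes("genotype_error", seed=4, n_genomes=2,
                                n_chrom=2, chrom_length=1_000_000)
        total = sum(len(p) for d in data.injected_errors.values()
                    for p in d.values())
        lam = 1e-5 * 2 * 2 * 1_000_000
        assert abs(total - lam) < 5 * np.sqrt(lam)
        # injected positions really are heterozygous in the profiles
        prof = {p.sample_id: p for p in data.profiles}
        for sample, d in data.injected_errors.items():
            for chrom, pos in d.items():
                assert np.all(np.isin(pos, prof[sample].het_positions[chrom]))

    def test_model_violation_scenarios_run(self):
        for scen in ("variable_mu", "admixture", "combined"):
            data = scenario_genomes(scen, seed=5, n_genomes=2, n_chrom=2,
                                    chrom_length=500_000)
            assert sum(p.n_het() for p in data.profiles) > 0
            if scen == "combined":
                assert data.truth["genotype_error_rate"] == pytest.approx(1 / 150_000)
                assert data.truth["admixture"] and data.truth["variable_mu"]

    def test_same_seed_reproduces_data(self):
        a = scenario_genomes("baseline", seed=9, n_genomes=2, n_chrom=2,
                             chrom_length=400_000)
        b = scenario_genomes("baseline", seed=9, n_genomes=2, n_chrom=2,
                             chrom_length=400_000)
        for pa, pb in zip(a.profiles, b.profiles):
            for chrom in pa.het_positions:
                assert np.array_equal(pa.het_positions[chrom], pb.het_positions[chrom])

    def test_save_load_roundtrip(self, tmp_path, baseline_data):
        baseline_data.save(str(tmp_path / "d"))
        back = type(baseline_data).load(str(tmp_path / "d"))
        assert back.scenario == "baseline"
        assert back.truth["mu_true"] == 2.5e-8
        pa, pb = baseline_data.profiles[0], back.profiles[0]
        assert np.array_equal(pa.het_positions["chr1"], pb.het_positions["chr1"])
        assert back.demography.theta == pytest.approx(baseline_data.demography.theta)


class TestSuperRegionSimulation:
    def test_zero_genetic_length_region_rejected(self, constant_map):
        from mucal.ascertainment import StartingPoint, SuperRegion
        from mucal.map_model import GeneticMap

        flat = GeneticMap({"chr1": (np.array([0, 1_000_000]), np.array([0.0, 0.0]))})
        pt = StartingPoint("g", "chr1", 500_000, 7, 100_000)
        region = SuperRegion("chr1", 400_000, 600_000, [pt])
        cfg = SimConfig(mu_sim=2.5e-8, gmap=flat, n_genomes=1)
        dem = Demography(theta=1e-3, n_baseline=10_000)
        with pytest.raises(ValueError, match="zero genetic length"):
            simulate_super_region(region, dem, cfg)

    def test_positions_fall_inside_region(self, constant_map, flat_demography):
        from mucal.ascertainment import StartingPoint, SuperRegion

        pt = StartingPoint("g", "chr1", 1_000_000, 7, 100_000)
        region = SuperRegion("chr1", 900_000, 1_100_000, [pt])
        cfg = SimConfig(mu_sim=2.5e-8, gmap=constant_map, n_genomes=2)
        hets = simulate_super_region(region, flat_demography, cfg,
                                     rng=np.random.default_rng(3))
        for h in hets:
            if len(h):
                assert h.min() >= region.start and h.max() < region.end
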