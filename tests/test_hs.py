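import numpy as np
import pytest

from mucal.ascertainment import SuperRegion, StartingPoint, ascertain, \
    define_super_regions, tile_and_count
from mucal.hs import (CurveValues, HSCurve, N_BINS, asymptote_adjust,
                      compute_curve)
from tests.test_ascertainment import make_profile


def one_region(constant_map, het, sample="g0", mid=1_050_000):
    pt = StartingPoint(sample, "chr1", mid, 7, 100_000)
    return SuperRegion("chr1", mid - 80_000, mid + 80_000, [pt])


class TestCurveComputation:
    def test_zero_het_gives_flat_zero_curve(self, constant_map):
        prof = make_profile({"chr1": []}, {"chr1": 2_000_000})
        region = one_region(constant_map, [])
        curve = compute_curve([prof], [region], constant_map)
        assert np.all(curve.h() == 0)
        assert curve.n_points == 1

    def test_no_regions_is_error(self, constant_map):
        prof = make_profile({"chr1": []}, {"chr1": 2_000_000})
        with pytest.raises(ValueError):
            compute_curve([prof], [], constant_map)

    def test_bin_count_is_sixty_over_tenth_cm(self, constant_map):
        prof = make_profile({"chr1": [1_050_000]}, {"chr1": 2_000_000})
        curve = compute_curve([prof], [one_region(constant_map, [])], constant_map)
        assert curve.n_bins == N_BINS == 60
        assert curve.bin_edges[0] == 0.0 and curve.bin_edges[-1] == pytest.approx(0.1)

    def test_brute_force_binning_oracle(self, constant_map, rng):
        mid = 1_050_000
        het = np.sort(rng.choice(np.arange(mid - 80_000, mid + 80_000),
                                 size=60, replace=False))
        mask = np.array([[mid + 20_000, mid + 21_000]])
        prof = make_profile({"chr1": het[~((het >= mid + 20_000) & (het < mid + 21_000))]},
                            {"chr1": 2_000_000}, masks={"chr1": mask.tolist()})
        region = one_region(constant_map, het)
        curve = compute_curve([prof], [region], constant_map)
        # brute force: per-site distance loop on the constant 1.25 cM/Mb map
        delta = 0.1 / 60
        exp_sites = np.zeros(60)
        exp_het = np.zeros(60)
        het_set = set(prof.het_positions["chr1"].tolist())
        for p in range(region.start, region.end):
            d = abs(p - mid) * 1.25e-6
            if d >= 0.1:
                continue
            b = int(d / delta)
            if mask[0, 0] <= p < mask[0, 1]:
                continue
            exp_sites[b] += 1
            if p in het_set:
                exp_het[b] += 1
        got = curve._chrom["chr1"]
        # identical totals; sites exactly on a bin boundary may round to
        # either neighbour under the map-grid interpolation
        assert abs(got["het"].sum() - exp_het.sum()) <= 1
        assert abs(got["sites"].sum() - exp_sites.sum()) <= 2
        assert np.abs(np.cumsum(got["het"]) - np.cumsum(exp_het)).max() <= 1
        assert np.abs(np.cumsum(got["sites"]) - np.cumsum(exp_sites)).max() <= 2

    def test_site_exactly_at_limit_excluded(self, constant_map):
        mid = 1_050_000
        region = one_region(constant_map, [])
        prof = make_profile({"chr1": [mid + 80_000 - 1]}, {"chr1": 2_000_000})
        curve = compute_curve([prof], [region], constant_map)
        # 79,999 bases * 1.25e-6 cM = 0.0999...  -> last bin
        assert curve._chrom["chr1"]["het"][59] == 1

    def test_invariant_to_genome_and_region_order(self, constant_map, rng):
        profs = []
        regions = []
        for k, mid in enumerate((300_000, 1_050_000)):
            het = np.sort(rng.choice(
                np.arange(mid - 80_000, mid + 80_000), size=30, replace=False))
            profs.append(make_profile({"chr1": het}, {"chr1": 2_000_000},
                                      sample=f"g{k}"))
            pt = StartingPoint(f"g{k}", "chr1", mid, 7, 100_000)
            regions.append(SuperRegion("chr1", mid - 80_000, mid + 80_000, [pt]))
        c1 = compute_curve(profs, regions, constant_map)
        c2 = compute_curve(profs[::-1], regions[::-1], constant_map)
        assert np.allclose(c1.h(), c2.h())
        assert c1.h0() == c2.h0()


class TestAsymptoteAdjustment:
    def _curve(self):
        h = np.linspace(7e-5, 4e-4, 60)
        return CurveValues(h, 7e-5)

    def test_ratio_one_is_identity(self):
        c = self._curve()
        adj = asymptote_adjust(c, 5e-4, 5e-4)
        assert np.allclose(adj.h, c.h)

    def test_scaling_of_relaxation_portion(self):
        c = self._curve()
        adj = asymptote_adjust(c, 5.25e-4, 5e-4)   # ratio 1.05
        assert np.allclose(adj.h - c.h0, (c.h - c.h0) * 1.05)

    def test_intercept_invariant_for_any_ratio(self):
        c = self._curve()
        for ratio in (0.6, 1.0, 1.9):
            adj = asymptote_adjust(c, ratio * 5e-4, 5e-4)
            assert adj.h[0] == pytest.approx(c.h0 + (c.h[0] - c.h0) * ratio)
            assert adj.h0 == c.h0

    def test_extreme_ratio_warns(self):
        with pytest.warns(UserWarning, match="ratio"):
            asymptote_adjust(self._curve(), 5e-4, 1.2e-3)

    def test_nonpositive_means_rejected(self):
        with pytest.raises(ValueError):
            asymptote_adjust(self._curve(), 0.0, 5e-4)


class TestRelaxationProperties:
    def test_curve_relaxes_toward_span_mean(self, baseline_data):
        """On simulated data the curve rises from H_S(0) toward the
        unconditional span mean as genetic distance grows."""
        pts = ascertain(tile_and_count(baseline_data.profiles))
        regions = define_super_regions(pts, baseline_data.base_map)
        curve = compute_curve(baseline_data.profiles, regions, baseline_data.base_map)
        h = curve.h()
        decades = [h[i:i + 10].mean() for i in range(0, 60, 10)]
        # monotone in expectation: each decade at least as high as two before
        for k in range(2, 6):
            assert decades[k] >= decades[k - 2] * 0.8
        assert decades[5] > 2.5 * decades[0]
        # far end approaches the span mean (tolerance: finite 0.1 cM horizon)
        assert decades[5] >= 0.4 * curve.hbar()
        assert curve.h0() < 0.25 * curve.hbar()

    def test_jackknife_bin_variances_positive_where_counted(self, baseline_data):
        pts = ascertain(tile_and_count(baseline_data.profiles))
        regions = define_super_regions(pts, baseline_data.base_map)
        curve = compute_curve(baseline_data.profiles, regions, baseline_data.base_map)
        var = curve.bin_variances()
        assert var.shape == (60,)
        assert np.nanmax(var) > 0

    def test_leave_one_out_consistency(self, baseline_data):
        pts = ascertain(tile_and_count(baseline_data.profiles))
        regions = define_super_regions(pts, baseline_data.base_map)
        curve = compute_curve(baseline_data.profiles, regions, baseline_data.base_map)
        chrom = curve.chromosomes[0]
        vals = curve.without(chrom)
        # removing a chromosome's accumulators equals recomputing without it
        sub = [r for r in regions if r.chrom != chrom]
        redone = compute_curve(baseline_data.profiles, sub, baseline_data.base_map)
        assert np.allclose(vals.h, redone.h())
        assert vals.h0 == pytest.approx(redone.h0())
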