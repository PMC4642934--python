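import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def constant_map():
    """A two-chromosome map at a uniform 1.25 cM/Mb."""
    from mucal.map_model import GeneticMap

    grids = {}
    for chrom in ("chr1", "chr2"):
        pos = np.arange(0, 2_000_001, 10_000)
        grids[chrom] = (pos, pos * 1.25e-6)
    return GeneticMap(grids)


@pytest.fixture(scope="session")
def desk_lite():
    """A reduced scale profile for fast end-to-end tests."""
    import dataclasses

    from mucal.harness import scale_profile

    return dataclasses.replace(
        scale_profile("desk"), n_genomes=3, n_chrom=8, chrom_length=2_000_000,
        calib_genomes=6, calib_region_cap=60, n_calibrations=1, n_trials=1)


@pytest.fixture(scope="session")
def baseline_data():
    """One small baseline scenario data set shared across tests."""
    from mucal.coalescent import scenario_genomes

    return scenario_genomes("baseline", seed=777, n_genomes=3, n_chrom=8,
                            chrom_length=2_000_000)


def write_vcf(path, records, samples=("S1",), contigs=(("chr1", 1000),)):
    """Write a minimal plain-text VCF with PL and DP fields.

    ``records`` rows: (chrom, pos1, ref, alt, [(pl_tuple, dp), ...]) with one
    per-sample entry; ``alt`` may hold commas for multi-allelic sites.
    """
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##INFO=<ID=MQ,Number=1,Type=Float,Description="mapq">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">')
    lines.append('##FORMAT=<ID=PL,Number=G,Type=Integer,Description="pl">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for rec in records:
        chrom, pos, ref, alt, per_sample = rec[:5]
        mq = rec[5] if len(rec) > 5 else 60.0
        cols = [chrom, str(pos), ".", ref, alt, ".", ".", f"MQ={mq}", "GT:PL:DP"]
        for pl, dp in per_sample:
            gt = "0/1" if pl[1] <= min(pl[0], pl[2]) else ("0/0" if pl[0] < pl[2] else "1/1")
            cols.append(f"{gt}:{','.join(str(int(x)) for x in pl)}:{dp}")
        lines.append("\t".join(cols))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
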