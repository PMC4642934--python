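"""Reading diploid genotype calls into per-genome heterozygosity profiles.

The quality scheme works directly on genotype likelihoods (PL): the
heterozygote PL is compared with the minimum of the two homozygote PLs,
with a quality threshold Q and a prior offset P reflecting the genome-wide
average heterozygosity.  A site is called heterozygous only if the
heterozygote is at least Q+P more likely (in PL units), homozygous if the
homozygote is at least Q-P more likely, and masked otherwise.  Site-level
masks (tandem repeats, alignability, coverage extremes, low quality) are
pooled, dilated by a couple of bases, and removed from the callable set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from . import intervals as iv

__all__ = [
    "GenotypeCall",
    "FilterConfig",
    "HetProfile",
    "call_genotype",
    "build_coverage_mask",
    "dilate_mask",
    "read_bed",
    "read_profiles",
]


class GenotypeCall(Enum):
    HET = "HET"
    HOM = "HOM"
    MASKED = "MASKED"


@dataclass
class FilterConfig:
    """Site-filtering thresholds.

    quality_threshold (Q) and het_prior_offset (P) define the PL decision
    band: HET iff PL(hom_min) - PL(het) >= Q + P, HOM iff
    PL(het) - PL(hom_min) >= Q - P, masked in between.
    """

    mapping_quality: float = 30.0
    quality_threshold: int = 60
    het_prior_offset: int = 31
    coverage_central_mass: float = 0.95
    dilation_radius: int = 2
    external_mask_paths: list = field(default_factory=list)

    def __post_init__(self):
        if self.quality_threshold <= 0:
            raise ValueError("quality threshold must be > 0")
        if not 0 < self.coverage_central_mass < 1:
            raise ValueError("central mass must be in (0, 1)")
        if self.dilation_radius < 0:
            raise ValueError("dilation radius must be >= 0")


@dataclass
class HetProfile:
    """One diploid genome's called heterozygous sites and mask per chromosome.

    het_positions : chrom -> sorted 0-based physical positions of
        heterozygous calls (never inside the mask).
    mask : chrom -> merged 0-based half-open excluded intervals.
    callable_count : chrom -> number of unmasked analyzable sites.
    chrom_lengths : chrom -> chromosome length in bases.
    het_is_cpg : optional chrom -> bool array aligned with het_positions
        (True for C-to-T transitions at CpG sites, when a reference was
        available at read time).
    """

    sample_id: str
    het_positions: dict[str, np.ndarray] = field(default_factory=dict)
    mask: dict[str, np.ndarray] = field(default_factory=dict)
    callable_count: dict[str, int] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    het_is_cpg: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        for chrom, pos in self.het_positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: het positions must be strictly increasing")
            m = self.mask.get(chrom, np.empty((0, 2), dtype=np.int64))
            m = iv.merge(m)
            if np.any(iv.contains(m, pos)):
                raise ValueError(f"{chrom}: heterozygous site inside mask")
            self.het_positions[chrom] = pos
            self.mask[chrom] = m
            length = self.chrom_lengths.get(chrom)
            if length is not None and self.callable_count.get(chrom, 0) > length:
                raise ValueError(f"{chrom}: callable count exceeds chromosome length")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.het_positions)

    def n_het(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.het_positions[chrom])
        return sum(len(v) for v in self.het_positions.values())

    def to_tsv(self, path: str) -> None:
        rows = []
        for chrom, pos in self.het_positions.items():
            for p in pos:
                rows.append((chrom, int(p)))
        pd.DataFrame(rows, columns=["chrom", "pos"]).to_csv(path, sep="\t", index=False)


def call_genotype(pl_het: int, pl_hom_min: int, config: FilterConfig | None = None) -> GenotypeCall:
    """Classify a site from its heterozygote PL and minimum homozygote PL.

    PL scores are non-negative scaled likelihoods (smaller = more likely).
    """
    config = config or FilterConfig()
    if pl_het < 0 or pl_hom_min < 0:
        raise ValueError("negative PL score")
    q, p = config.quality_threshold, config.het_prior_offset
    if pl_hom_min - pl_het >= q + p:
        return GenotypeCall.HET
    if pl_het - pl_hom_min >= q - p:
        return GenotypeCall.HOM
    return GenotypeCall.MASKED


def coverage_thresholds(depths, config: FilterConfig | None = None) -> tuple[int, int]:
    """Nearest-rank depth cutoffs [lo, hi] retaining the central mass."""
    config = config or FilterConfig()
    d = np.asarray(depths, dtype=np.int64)
    if d.size == 0:
        raise ValueError("empty depth input")
    a = (1.0 - config.coverage_central_mass) / 2.0
    srt = np.sort(d)
    k_lo = max(int(np.ceil(a * d.size)), 1)
    k_hi = max(int(np.ceil((1 - a) * d.size)), 1)
    return int(srt[k_lo - 1]), int(srt[k_hi - 1])


def build_coverage_mask(depths, config: FilterConfig | None = None) -> np.ndarray:
    """Mask sites whose depth falls outside the central mass of the genome's
    depth distribution (default: outside the central 95%).

    Thresholds use the nearest-rank convention: with n sites and tail mass
    a on each side, the cutoffs are the ceil(a*n)-th and ceil((1-a)*n)-th
    order statistics; sites strictly outside [lo, hi] are masked.  Depths
    are per-genome, so two genomes get independent masks.
    """
    config = config or FilterConfig()
    d = np.asarray(depths, dtype=np.int64)
    lo, hi = coverage_thresholds(d, config)
    bad = np.flatnonzero((d < lo) | (d > hi))
    if bad.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    return iv.merge(np.column_stack([bad, bad + 1]))


def dilate_mask(mask, radius: int, chrom_length: int | None = None) -> np.ndarray:
    """Mask every position within ``radius`` bases of a masked base."""
    return iv.dilate(mask, radius, lo=0, hi=chrom_length)


def read_fasta(path: str) -> dict[str, str]:
    """Reference sequences as a chrom -> string mapping (for CpG context)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def read_bed(path: str) -> dict[str, np.ndarray]:
    """Read a BED file into per-chromosome merged interval arrays."""
    out: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            out.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return {c: iv.merge(np.array(v, dtype=np.int64)) for c, v in out.items()}


def _classify_cpg(refseq: str, pos0: int, ref: str, alts: tuple) -> bool:
    """Is this biallelic het a C-to-T transition at a CpG site (either strand)?"""
    alleles = {ref.upper()} | {a.upper() for a in alts}
    if alleles == {"C", "T"} and pos0 + 1 < len(refseq):
        return refseq[pos0].upper() == "C" and refseq[pos0 + 1].upper() == "G"
    if alleles == {"G", "A"} and pos0 >= 1:
        return refseq[pos0].upper() == "G" and refseq[pos0 - 1].upper() == "C"
    return False


def read_profiles(
    vcf_paths,
    mask_paths=(),
    config: FilterConfig | None = None,
    reference=None,
) -> list[HetProfile]:
    """Stream VCFs (one or more samples each) into HetProfiles.

    The VCF is expected to carry genotype likelihoods (PL) and per-sample
    depth (DP) for every analyzable site; VCF 1-based positions are
    converted to 0-based internally.  The full mask is the union of the
    external BED masks, the per-genome coverage mask, the low-mapping-
    quality and quality-band masks, dilated by ``config.dilation_radius``.
    Multi-allelic sites are masked (the method models biallelic
    heterozygosity only).

    ``reference``, if given, is a mapping chrom -> sequence string used to
    classify heterozygous calls as CpG transitions.
    """
    import pysam

    config = config or FilterConfig()
    ext_masks = [read_bed(p) for p in list(mask_paths) + list(config.external_mask_paths)]

    profiles: list[HetProfile] = []
    for path in vcf_paths:
        with pysam.VariantFile(path) as vf:
            contigs = {c: vf.header.contigs[c].length or 0 for c in vf.header.contigs}
            for em in ext_masks:
                missing = sorted(set(em) - set(contigs))
                if missing:
                    raise ValueError(
                        f"contig name mismatch between VCF and mask: {missing}")
            samples = list(vf.header.samples)
            state = {
                s: {"het": {}, "pos_seen": {}, "depth": {}, "bad": {}, "cpg": {}, "warn": 0}
                for s in samples
            }
            for rec in vf:
                chrom, pos0 = rec.chrom, rec.pos - 1
                multiallelic = rec.alts is not None and len(rec.alts) > 1
                mq = rec.info.get("MQ", None)
                low_mq = mq is not None and mq < config.mapping_quality
                for s in samples:
                    st = state[s]
                    fmt = rec.samples[s]
                    st["pos_seen"].setdefault(chrom, []).append(pos0)
                    st["depth"].setdefault(chrom, []).append(fmt.get("DP") or 0)
                    if multiallelic or low_mq:
                        st["bad"].setdefault(chrom, []).append(pos0)
                        continue
                    pl = fmt.get("PL")
                    if pl is None or len(pl) < 3 or any(x is None for x in pl[:3]):
                        st["bad"].setdefault(chrom, []).append(pos0)
                        continue
                    pl_het, pl_hom = pl[1], min(pl[0], pl[2])
                    try:
                        call = call_genotype(pl_het, pl_hom, config)
                    except ValueError:
                        st["warn"] += 1
                        st["bad"].setdefault(chrom, []).append(pos0)
                        continue
                    if call is GenotypeCall.MASKED:
                        st["bad"].setdefault(chrom, []).append(pos0)
                    elif call is GenotypeCall.HET:
                        st["het"].setdefault(chrom, []).append(pos0)
                        if reference is not None and chrom in reference:
                            st["cpg"].setdefault(chrom, []).append(
                                _classify_cpg(reference[chrom], pos0, rec.ref, rec.alts or ()))

            for s in samples:
                st = state[s]
                profiles.append(_assemble_profile(s, st, contigs, ext_masks, config,
                                                  with_cpg=reference is not None))
                if st["warn"]:
                    warnings.warn(f"{s}: rejected {st['warn']} records with negative PL")
    return profiles


def _assemble_profile(sample, st, contigs, ext_masks, config, with_cpg=False):
    het_positions, masks, callable_count, lengths = {}, {}, {}, {}
    cpg_flags = {} if with_cpg else None
    all_depths = np.concatenate([np.asarray(v) for v in st["depth"].values()])
    lo, hi = coverage_thresholds(all_depths, config)  # genome-specific band
    for chrom, seen in st["pos_seen"].items():
        seen = np.asarray(seen, dtype=np.int64)
        length = contigs.get(chrom) or int(seen.max()) + 1
        depth = np.asarray(st["depth"][chrom], dtype=np.int64)
        cov_pos = seen[(depth < lo) | (depth > hi)]
        cov_ivals = (np.column_stack([cov_pos, cov_pos + 1]) if cov_pos.size else
                     np.empty((0, 2), dtype=np.int64))
        bad = np.asarray(st["bad"].get(chrom, []), dtype=np.int64)
        bad_ivals = (np.column_stack([bad, bad + 1]) if bad.size else
                     np.empty((0, 2), dtype=np.int64))
        parts = [em.get(chrom, np.empty((0, 2), dtype=np.int64)) for em in ext_masks]
        full = iv.union(cov_ivals, bad_ivals, *parts)
        full = dilate_mask(full, config.dilation_radius, length)
        keep = ~iv.contains(full, seen)
        het = np.asarray(st["het"].get(chrom, []), dtype=np.int64)
        het_keep = ~iv.contains(full, het)
        het_positions[chrom] = het[het_keep]
        if cpg_flags is not None:
            flags = np.asarray(st["cpg"].get(chrom, []), dtype=bool)
            cpg_flags[chrom] = flags[het_keep] if flags.size == het.size else np.zeros(het_keep.sum(), bool)
        masks[chrom] = full
        callable_count[chrom] = int(keep.sum())
        lengths[chrom] = length
    return HetProfile(sample, het_positions, masks, callable_count, lengths,
                      het_is_cpg=cpg_flags)
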