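"""The heterozygosity-relaxation statistic H_S(d).

H_S(d) is the average heterozygosity (pooled heterozygous sites over
pooled unmasked sites) as a function of genetic distance d from a set of
ascertained starting points, computed in 60 half-open distance bins
[k*D, (k+1)*D) with D = 0.1/60 cM; a site exactly at 0.1 cM is excluded.
Both directions from a starting point contribute to the same bins.  The
d = 0 anchor H_S(0) is the pooled heterozygosity of the ascertained
windows themselves, not the first bin's value.

Accumulators are kept per chromosome so that leave-one-chromosome-out
quantities (per-bin variances for the weighted fit, and the jackknife of
the full estimate) are cheap arithmetic rather than recomputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as iv
from .map_model import GeneticMap

__all__ = ["HSCurve", "CurveValues", "RegionGeometry", "region_geometry",
           "compute_curve", "asymptote_adjust", "N_BINS", "D_MAX_CM"]

N_BINS = 60
D_MAX_CM = 0.1


@dataclass
class CurveValues:
    """A plain relaxation curve: per-bin H plus the d=0 anchor."""

    h: np.ndarray
    h0: float

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)


class RegionGeometry:
    """Distance-bin assignment of every site in one super-region.

    Precomputes, for the span [start, end) around a midpoint, the bin
    index of each integer position under the supplied map, so repeated
    curve accumulation over the same region (e.g. for a calibration mu
    grid) costs one array lookup.
    """

    def __init__(self, gmap: GeneticMap, chrom: str, start: int, end: int,
                 midpoint: int, n_bins: int = N_BINS, d_max_cm: float = D_MAX_CM):
        self.chrom, self.start, self.end = chrom, start, end
        self.n_bins = n_bins
        delta = d_max_cm / n_bins
        pos = np.arange(start, end, dtype=np.int64)
        cm = gmap.interpolate(chrom, pos)
        cm_mid = float(gmap.interpolate(chrom, midpoint)[0])
        d = np.abs(cm - cm_mid)
        bins = np.floor(d / delta).astype(np.int64)
        self._bins = np.where(d < d_max_cm, bins, -1)  # -1 = beyond 0.1 cM
        valid = self._bins >= 0
        self.site_counts = np.bincount(self._bins[valid], minlength=n_bins).astype(float)

    def bin_of(self, positions: np.ndarray) -> np.ndarray:
        """Bin index (or -1) for absolute positions inside the span."""
        p = np.asarray(positions, dtype=np.int64)
        inside = (p >= self.start) & (p < self.end)
        out = np.full(p.shape, -1, dtype=np.int64)
        out[inside] = self._bins[p[inside] - self.start]
        return out

    def bincount(self, positions: np.ndarray) -> np.ndarray:
        b = self.bin_of(positions)
        b = b[b >= 0]
        return np.bincount(b, minlength=self.n_bins).astype(float)


def region_geometry(gmap, region, cache: dict | None = None) -> RegionGeometry:
    """Geometry for a SuperRegion (memoized in ``cache`` when given)."""
    mid = region.points[0].midpoint
    key = (id(gmap), region.chrom, region.start, region.end, mid)
    if cache is not None and key in cache:
        return cache[key]
    geo = RegionGeometry(gmap, region.chrom, region.start, region.end, mid)
    if cache is not None:
        cache[key] = geo
    return geo


class HSCurve:
    """Binned relaxation curve with per-chromosome accumulators."""

    FIELDS = ("h0_het", "h0_sites", "hbar_het", "hbar_sites", "n_points")

    def __init__(self, n_bins: int = N_BINS, d_max_cm: float = D_MAX_CM):
        self.n_bins = n_bins
        self.d_max_cm = d_max_cm
        self.bin_edges = np.linspace(0.0, d_max_cm, n_bins + 1)
        self._chrom: dict[str, dict] = {}

    # -- accumulation ------------------------------------------------------

    def _entry(self, chrom: str) -> dict:
        if chrom not in self._chrom:
            self._chrom[chrom] = {
                "het": np.zeros(self.n_bins), "sites": np.zeros(self.n_bins),
                "h0_het": 0.0, "h0_sites": 0.0,
                "hbar_het": 0.0, "hbar_sites": 0.0, "n_points": 0,
            }
        return self._chrom[chrom]

    def add(self, chrom: str, *, het=None, sites=None, h0_het=0.0, h0_sites=0.0,
            hbar_het=0.0, hbar_sites=0.0, n_points=0) -> None:
        e = self._entry(chrom)
        if het is not None:
            e["het"] += het
        if sites is not None:
            e["sites"] += sites
        e["h0_het"] += h0_het
        e["h0_sites"] += h0_sites
        e["hbar_het"] += hbar_het
        e["hbar_sites"] += hbar_sites
        e["n_points"] += n_points

    # -- totals ------------------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return [c for c, e in self._chrom.items() if e["n_points"] > 0]

    def _sum(self, key: str, exclude: str | None = None):
        vals = [e[key] for c, e in self._chrom.items() if c != exclude]
        if not vals:
            return np.zeros(self.n_bins) if key in ("het", "sites") else 0.0
        return np.sum(vals, axis=0)

    def h(self, exclude: str | None = None) -> np.ndarray:
        het = self._sum("het", exclude)
        sites = self._sum("sites", exclude)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sites > 0, het / np.maximum(sites, 1), 0.0)
        return out

    def h0(self, exclude: str | None = None) -> float:
        s = self._sum("h0_sites", exclude)
        return float(self._sum("h0_het", exclude) / s) if s > 0 else 0.0

    def hbar(self, exclude: str | None = None) -> float:
        """Mean heterozygosity over the super-regions feeding the curve."""
        s = self._sum("hbar_sites", exclude)
        return float(self._sum("hbar_het", exclude) / s) if s > 0 else 0.0

    @property
    def n_points(self) -> int:
        return int(self._sum("n_points"))

    def values(self) -> CurveValues:
        return CurveValues(self.h(), self.h0())

    def without(self, chrom: str) -> CurveValues:
        return CurveValues(self.h(exclude=chrom), self.h0(exclude=chrom))

    def points_per_chrom(self) -> dict[str, int]:
        return {c: int(e["n_points"]) for c, e in self._chrom.items() if e["n_points"] > 0}

    # -- uncertainty -------------------------------------------------------

    def bin_variances(self) -> np.ndarray:
        """Per-bin variance of H by leave-one-chromosome-out jackknife."""
        chroms = self.chromosomes
        g = len(chroms)
        if g < 2:
            return np.full(self.n_bins, np.nan)
        loo = np.array([self.h(exclude=c) for c in chroms])
        mean = loo.mean(axis=0)
        return (g - 1) / g * ((loo - mean) ** 2).sum(axis=0)

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        h = self.h()
        var = self.bin_variances()
        het = self._sum("het")
        sites = self._sum("sites")
        return pd.DataFrame({
            "bin_lo_cM": self.bin_edges[:-1], "bin_hi_cM": self.bin_edges[1:],
            "n_sites": sites, "n_het": het, "H": h, "var": var,
        })

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def compute_curve(
    profiles,
    regions,
    gmap: GeneticMap,
    cache: dict | None = None,
) -> HSCurve:
    """Compute the observed H_S(d) curve for ascertained super-regions.

    Every unmasked site within a region's span contributes to the bin of
    its absolute genetic distance (on ``gmap``) from the region midpoint;
    heterozygous sites of the genome that contributed the starting point
    are counted in the numerator.  H_S(0) pools the ascertainment
    windows.  The region-mean heterozygosity (feeding the asymptote
    adjustment) pools the *other* genomes over the span: the owner is
    conditioned low by ascertainment, so including it would bias the
    unconditional span mean that the matching simulated value estimates.
    With a single genome the owner itself is used as a fallback.

    Raises when there are no starting points.
    """
    if not regions:
        raise ValueError("no starting points / super-regions supplied")
    by_id = {p.sample_id: p for p in profiles}
    curve = HSCurve()
    for region in regions:
        pt = region.points[0]
        prof = by_id[pt.sample_id]
        geo = region_geometry(gmap, region, cache)
        site_counts = geo.site_counts.copy()
        mask = prof.mask.get(region.chrom, np.empty((0, 2), dtype=np.int64))
        if len(mask):
            clipped = iv.clip(mask, region.start, region.end)
            if len(clipped):
                mpos = np.concatenate([np.arange(s, e) for s, e in clipped])
                site_counts -= geo.bincount(mpos)
        het = prof.het_positions.get(region.chrom, np.empty(0, dtype=np.int64))
        i, j = np.searchsorted(het, [region.start, region.end])
        het_in_span = het[i:j]
        hbar_het = hbar_sites = 0.0
        for other in profiles:
            if other.sample_id == pt.sample_id and len(profiles) > 1:
                continue
            o_het = other.het_positions.get(region.chrom, np.empty(0, dtype=np.int64))
            oi, oj = np.searchsorted(o_het, [region.start, region.end])
            o_mask = other.mask.get(region.chrom, np.empty((0, 2), dtype=np.int64))
            masked = iv.total_length(iv.clip(o_mask, region.start, region.end)) if len(o_mask) else 0
            hbar_het += oj - oi
            hbar_sites += region.length - masked
        curve.add(
            region.chrom,
            het=geo.bincount(het_in_span),
            sites=site_counts,
            h0_het=pt.n_het, h0_sites=pt.n_unmasked,
            hbar_het=hbar_het, hbar_sites=hbar_sites,
            n_points=1,
        )
    return curve


def asymptote_adjust(curve: HSCurve | CurveValues, hbar_real: float,
                     hbar_sim: float) -> CurveValues:
    """Rescale the relaxation portion of a calibration curve.

    H'(d) = H(0) + (H(d) - H(0)) * (hbar_real / hbar_sim); the intercept
    is unchanged.  This aligns the curve asymptote with the data when the
    demographic model does not reproduce the mean heterozygosity exactly;
    in practice the correction is within about 10%.
    """
    if hbar_real <= 0 or hbar_sim <= 0:
        raise ValueError("mean heterozygosities must be positive")
    ratio = hbar_real / hbar_sim
    if not 0.5 <= ratio <= 2.0:
        warnings.warn(f"asymptote ratio {ratio:.3g} outside [0.5, 2]")
    vals = curve.values() if isinstance(curve, HSCurve) else curve
    return CurveValues(vals.h0 + (vals.h - vals.h0) * ratio, vals.h0)
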