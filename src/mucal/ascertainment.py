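"""Window tiling, starting-point ascertainment, and super-region definition.

The genome is tiled with non-overlapping 100-kb windows (physical
coordinates).  Windows whose heterozygous-site count lies in a chosen
range S (default 5-10 per 100 kb, i.e. local heterozygosity around
7.5e-5) and that carry at least one heterozygous site in each half become
starting points at their midpoints.  Around each starting point a
"super-region" is defined extending at least 0.1 cM on both sides on the
base genetic map; these are the units simulated when building calibration
curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv
from .genomic_io import HetProfile
from .map_model import GeneticMap

__all__ = [
    "Window",
    "StartingPoint",
    "SuperRegion",
    "tile_and_count",
    "ascertain",
    "define_super_regions",
]

WINDOW_SIZE = 100_000


@dataclass
class Window:
    sample_id: str
    chrom: str
    start: int
    end: int
    n_unmasked: int
    n_het: int
    n_het_left: int
    n_het_right: int
    usable: bool  # False when more than half of the sites are masked

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class StartingPoint:
    sample_id: str
    chrom: str
    midpoint: int
    n_het: int
    n_unmasked: int


@dataclass
class SuperRegion:
    chrom: str
    start: int
    end: int
    points: list  # StartingPoints contained (one per region by construction)
    genetic_span_cm: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


def tile_and_count(
    profiles: list[HetProfile],
    window_size: int = WINDOW_SIZE,
) -> list[Window]:
    """Tile each genome's chromosomes and count heterozygous sites per window.

    Windows are counted per genome; a window is flagged unusable when more
    than 50% of its sites are masked.  Chromosomes shorter than one window
    produce no windows (with a warning).
    """
    out: list[Window] = []
    for prof in profiles:
        for chrom, length in prof.chrom_lengths.items():
            n_win = length // window_size
            if n_win == 0:
                warnings.warn(f"{prof.sample_id}/{chrom}: shorter than one window")
                continue
            het = prof.het_positions.get(chrom, np.empty(0, dtype=np.int64))
            mask = prof.mask.get(chrom, np.empty((0, 2), dtype=np.int64))
            edges = np.arange(n_win + 1, dtype=np.int64) * window_size
            half = np.arange(n_win, dtype=np.int64) * window_size + window_size // 2
            masked_below = iv.masked_count_below(mask, edges)
            het_idx = np.searchsorted(het, edges)
            het_half = np.searchsorted(het, half)
            for k in range(n_win):
                masked = int(masked_below[k + 1] - masked_below[k])
                n_left = int(het_half[k] - het_idx[k])
                n_right = int(het_idx[k + 1] - het_half[k])
                out.append(Window(
                    sample_id=prof.sample_id, chrom=chrom,
                    start=int(edges[k]), end=int(edges[k + 1]),
                    n_unmasked=window_size - masked,
                    n_het=n_left + n_right,
                    n_het_left=n_left, n_het_right=n_right,
                    usable=masked <= window_size // 2,
                ))
    return out


def ascertain(
    windows: list[Window],
    s_range: tuple[float, float] = (5, 10),
    half_rule: bool = True,
) -> list[StartingPoint]:
    """Select starting points: midpoints of usable windows whose het count
    lies in the closed range S.

    ``half_rule`` additionally requires at least one heterozygous site in
    each half-window, guarding against windows whose heterozygosity comes
    from a single recombination near one end.  It is disabled for the
    CpG-only class mode, where windows hold a single class site.  Raw
    counts are compared against the (possibly fractional) bounds directly.
    """
    lo, hi = s_range
    points = []
    for w in windows:
        if not w.usable or not (lo <= w.n_het <= hi):
            continue
        if half_rule and (w.n_het_left < 1 or w.n_het_right < 1):
            continue
        points.append(StartingPoint(w.sample_id, w.chrom, w.midpoint, w.n_het, w.n_unmasked))
    if not points:
        raise ValueError(f"no eligible windows for S range {s_range}")
    return points


def define_super_regions(
    points: list[StartingPoint],
    base_map: GeneticMap,
    flank_cm: float = 0.1,
    window_size: int = WINDOW_SIZE,
) -> list[SuperRegion]:
    """Minimal physical spans with >= ``flank_cm`` genetic flank on each side.

    The span always contains the ascertainment window.  Points whose flank
    would run past the chromosome (map) ends are dropped with a warning:
    their relaxation curve could not be measured out to ``flank_cm``.
    """
    regions: list[SuperRegion] = []
    n_dropped = 0
    for pt in points:
        if pt.chrom not in base_map.grids:
            n_dropped += 1
            continue
        lo_map, hi_map = base_map.span(pt.chrom)
        if not (lo_map <= pt.midpoint <= hi_map):
            n_dropped += 1
            continue
        cm_mid = float(base_map.interpolate(pt.chrom, pt.midpoint)[0])
        pos_grid, cm_grid = base_map.grids[pt.chrom]
        if cm_mid - flank_cm < cm_grid[0] - 1e-12 or cm_mid + flank_cm > cm_grid[-1] + 1e-12:
            n_dropped += 1
            continue
        left = float(base_map.physical_at(pt.chrom, cm_mid - flank_cm)[0])
        right = float(base_map.physical_at(pt.chrom, cm_mid + flank_cm)[0])
        start = int(min(np.floor(left), pt.midpoint - window_size // 2))
        end = int(max(np.ceil(right), pt.midpoint + window_size // 2))
        start = max(start, lo_map)
        end = min(end, hi_map)
        span_cm = float(np.diff(base_map.interpolate(pt.chrom, [start, end]))[0])
        regions.append(SuperRegion(pt.chrom, start, end, [pt], span_cm))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} starting points truncated at map ends")
    return regions


def windows_to_frame(windows: list[Window]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample": w.sample_id, "chrom": w.chrom, "start": w.start, "end": w.end,
        "n_unmasked": w.n_unmasked, "n_het": w.n_het, "usable": w.usable,
    } for w in windows])
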