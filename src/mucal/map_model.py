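"""Genetic-map storage, interpolation, and the gamma error/perturbation model.

A genetic map is a per-chromosome grid of (physical position, cumulative
genetic position) pairs, as published for SNP-grid maps.  Genetic map
error is modelled with a gamma distribution: for a grid interval with
observed genetic length ``g`` (Morgans) and physical length ``p`` (bases),
the true length is taken as

    Z ~ Gamma(shape = alpha * g', rate = alpha),   g' = gamma * (g + pi * p)

so that E[Z] = g' and var(Z) = g'/alpha.  ``alpha`` (in 1/Morgan) measures
map accuracy: 1/alpha is the interval length at which the coefficient of
variation equals 1.  ``pi`` is a pseudo-count prior (genetic length per
physical length) compensating for underestimated very short intervals,
and ``gamma = G/(G + pi*P) < 1`` preserves the total map length.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneticMap",
    "MapErrorModel",
    "PerturbedMap",
    "interpret_alpha",
    "perturb",
    "synthetic_map",
]

CM_PER_MORGAN = 100.0


class GeneticMap:
    """Per-chromosome grids of physical (bp) vs cumulative genetic (cM) position.

    Parameters
    ----------
    grids : dict
        Mapping ``chrom -> (positions, cum_cM)`` where positions are a
        strictly increasing int array and cum_cM a matching non-decreasing
        float array.
    """

    def __init__(self, grids: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.grids: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, cm) in grids.items():
            pos = np.asarray(pos, dtype=np.int64)
            cm = np.asarray(cm, dtype=float)
            if len(pos) != len(cm) or len(pos) < 2:
                raise ValueError(f"{chrom}: grid needs >= 2 matching points")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: physical positions must be strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"{chrom}: cumulative cM must be non-decreasing")
            self.grids[chrom] = (pos, cm)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.grids)

    @property
    def total_cm(self) -> float:
        """Total map length G in cM."""
        return float(sum(cm[-1] - cm[0] for _, cm in self.grids.values()))

    @property
    def total_mb(self) -> float:
        """Total physical length P in Mb."""
        return float(sum(pos[-1] - pos[0] for pos, _ in self.grids.values())) / 1e6

    def span(self, chrom: str) -> tuple[int, int]:
        pos, _ = self.grids[chrom]
        return int(pos[0]), int(pos[-1])

    def interpolate(self, chrom: str, positions) -> np.ndarray:
        """Genetic position (cM) at physical positions, linear within the grid.

        Raises for positions outside the grid span; callers must truncate
        regions to the mapped extent first.
        """
        pos, cm = self.grids[chrom]
        q = np.atleast_1d(np.asarray(positions, dtype=float))
        if q.size and (q.min() < pos[0] or q.max() > pos[-1]):
            raise ValueError(f"position outside map grid span on {chrom}")
        return np.interp(q, pos, cm)

    def physical_at(self, chrom: str, cm_values) -> np.ndarray:
        """Inverse interpolation: physical position at genetic positions.

        Zero-rate stretches are inverted by adding a vanishing slope so the
        mapping is single-valued (leftmost position of a flat stretch).
        """
        pos, cm = self.grids[chrom]
        q = np.atleast_1d(np.asarray(cm_values, dtype=float))
        if q.size and (q.min() < cm[0] - 1e-12 or q.max() > cm[-1] + 1e-12):
            raise ValueError(f"genetic position outside map span on {chrom}")
        eps = np.arange(len(cm)) * 1e-13
        return np.interp(np.clip(q, cm[0], cm[-1]), cm + eps, pos)

    def interval_lengths(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-interval (physical bp, genetic Morgans) lengths."""
        pos, cm = self.grids[chrom]
        return np.diff(pos).astype(float), np.diff(cm) / CM_PER_MORGAN

    def rates_cm_per_mb(self, chrom: str) -> np.ndarray:
        p, g = self.interval_lengths(chrom)
        return (g * CM_PER_MORGAN) / (p / 1e6)

    def mean_rate_cm_per_mb(self) -> float:
        return self.total_cm / self.total_mb

    # --- serialization (tab-separated: chrom, pos, rate cM/Mb, cum cM) ---

    def to_tsv(self, path_or_buf) -> None:
        buf = open(path_or_buf, "w") if isinstance(path_or_buf, str) else path_or_buf
        try:
            buf.write("chrom\tposition\trate_cM_Mb\tmap_cM\n")
            for chrom, (pos, cm) in self.grids.items():
                rates = np.append(self.rates_cm_per_mb(chrom), 0.0)
                for p, r, c in zip(pos, rates, cm):
                    buf.write(f"{chrom}\t{p}\t{r:.8g}\t{c:.10g}\n")
        finally:
            if isinstance(path_or_buf, str):
                buf.close()

    @classmethod
    def from_tsv(cls, path_or_buf, chrom: str | None = None) -> "GeneticMap":
        """Read a map table.

        Accepts 4 columns (chrom, position, rate, cumulative cM) or the
        3-column single-chromosome dialect (position, rate, cumulative cM,
        ``chrom`` given by the caller).  A header line is tolerated.  The
        cumulative column is authoritative; the rate column is ignored.
        """
        buf = open(path_or_buf) if isinstance(path_or_buf, str) else path_or_buf
        try:
            grids: dict[str, list[tuple[int, float]]] = {}
            for line in buf:
                parts = line.split()
                if not parts:
                    continue
                try:
                    if len(parts) >= 4:
                        c, p, _, m = parts[0], int(parts[1]), parts[2], float(parts[3])
                    elif len(parts) == 3:
                        if chrom is None:
                            raise ValueError("3-column map requires an explicit chromosome name")
                        c, p, m = chrom, int(parts[0]), float(parts[2])
                    else:
                        continue
                except ValueError as err:
                    if "3-column" in str(err):
                        raise
                    continue  # header line
                grids.setdefault(c, []).append((p, m))
            return cls({c: (np.array([x[0] for x in v]), np.array([x[1] for x in v]))
                        for c, v in grids.items()})
        finally:
            if isinstance(path_or_buf, str):
                buf.close()


@dataclass
class MapErrorModel:
    """Gamma perturbation model for genetic-map error.

    alpha : map accuracy in 1/Morgan (default 3100, SE 300).
    pi_cm_per_mb : pseudo-count prior in cM/Mb (default 0.09).
    """

    alpha: float = 3100.0
    alpha_se: float = 300.0
    pi_cm_per_mb: float = 0.09

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.pi_cm_per_mb < 0:
            raise ValueError("pi must be >= 0")

    def gamma_factor(self, gmap: GeneticMap) -> float:
        """Total-length-preserving constant gamma = G/(G + pi*P), genome-wide."""
        G = gmap.total_cm
        P = gmap.total_mb
        g = G / (G + self.pi_cm_per_mb * P)
        if not 0 < g <= 1:
            raise ValueError("degenerate gamma factor")
        return g

    def prior_morgans_per_base(self) -> float:
        return self.pi_cm_per_mb / CM_PER_MORGAN / 1e6


class PerturbedMap(GeneticMap):
    """A gamma-perturbed realization of a parent map, on the same grid."""

    def __init__(self, grids, parent: GeneticMap, model: MapErrorModel, seed):
        super().__init__(grids)
        self.parent = parent
        self.model = model
        self.seed = seed


def interpret_alpha(alpha: float) -> float:
    """Length scale (cM) at which the map's coefficient of variation is 1.

    An interval of expected genetic length 1/alpha has SD equal to its mean
    under the gamma model; longer intervals are relatively better measured.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return CM_PER_MORGAN / alpha


def perturb(gmap: GeneticMap, model: MapErrorModel, seed_or_rng) -> PerturbedMap:
    """Draw a perturbed map: each interval length Z ~ Gamma(alpha*g', alpha).

    ``g' = gamma*(g + pi*p)`` in Morgans, so E[Z] = g', var(Z) = g'/alpha,
    and the expected total length equals the parent total length.  Grid
    physical positions are unchanged.  Zero-physical-length intervals
    cannot occur (grids are strictly increasing); zero-genetic-length
    intervals still receive positive expected length through the prior.
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    gam = model.gamma_factor(gmap)
    pi_m = model.prior_morgans_per_base()
    grids = {}
    for chrom, (pos, cm) in gmap.grids.items():
        p, g = gmap.interval_lengths(chrom)
        g_prime = gam * (g + pi_m * p)
        shape = model.alpha * g_prime
        z = np.where(shape > 0, rng.gamma(np.maximum(shape, 1e-300), 1.0 / model.alpha), 0.0)
        new_cm = cm[0] + np.concatenate([[0.0], np.cumsum(z)]) * CM_PER_MORGAN
        grids[chrom] = (pos.copy(), new_cm)
    return PerturbedMap(grids, gmap, model, seed_or_rng if not isinstance(seed_or_rng, np.random.Generator) else None)


def synthetic_map(
    chrom_lengths: dict[str, int],
    mean_rate_cm_per_mb: float = 1.25,
    grid_spacing: int = 2000,
    sigma_log: float = 0.7,
    zero_fraction: float = 0.10,
    seed: int = 0,
) -> GeneticMap:
    """Generate a heterogeneous SNP-grid recombination map.

    Interval rates are lognormal around the genome mean with a fraction of
    zero-length intervals (as observed in admixture- and pedigree-based
    maps), then rescaled so the realized mean rate equals
    ``mean_rate_cm_per_mb``.  The default mean of 1.25 cM/Mb matches the
    genome-wide human average (r = 1.25e-8 per base per generation).
    """
    rng = np.random.default_rng(seed)
    grids = {}
    for chrom, length in chrom_lengths.items():
        n = max(int(length // grid_spacing), 2)
        pos = np.linspace(0, length, n + 1).astype(np.int64)
        rates = rng.lognormal(mean=0.0, sigma=sigma_log, size=n)
        rates[rng.random(n) < zero_fraction] = 0.0
        p_mb = np.diff(pos) / 1e6
        g = rates * p_mb
        scale = mean_rate_cm_per_mb * p_mb.sum() / g.sum()
        cm = np.concatenate([[0.0], np.cumsum(g * scale)])
        grids[chrom] = (pos, cm)
    return GeneticMap(grids)
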