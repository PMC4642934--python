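"""Fitting the mutation rate against simulated calibration curves.

For each distance bin, the calibration curves define H(d; mu) at the grid
of simulated mutation rates (typically mu = 1, 2, 4 x 10^-8); a natural
cubic spline across the grid interpolates H(d; mu) in mu.  The observed
curve is then matched by variance-weighted least squares over the 60
bins (the d = 0 anchor is excluded: it is fixed by ascertainment in both
data sets), minimized over mu by a dense grid plus bounded local
refinement.  Uncertainty combines a leave-one-chromosome weighted
jackknife with independently propagated parameter uncertainties
(root-sum-of-squares under an independent-normal assumption).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar
from scipy.stats import linregress

from .hs import CurveValues, HSCurve

__all__ = [
    "CalibrationSet",
    "RateEstimate",
    "fit_mu",
    "average_calibrations",
    "weighted_jackknife",
    "propagate_alpha_uncertainty",
    "combine_uncertainty",
    "per_year_rate",
    "tmrca_of_het",
    "DEFAULT_MU_GRID",
    "CPG_MU_GRID",
]

DEFAULT_MU_GRID = (1e-8, 2e-8, 4e-8)
CPG_MU_GRID = (0.2e-8, 0.4e-8, 0.8e-8)


@dataclass
class CalibrationSet:
    """Adjusted calibration curves, one per grid mutation rate."""

    mu_grid: tuple
    curves: list[CurveValues]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.mu_grid) < 3:
            raise ValueError("need >= 3 calibration grid points")
        if len(self.curves) != len(self.mu_grid):
            raise ValueError("one curve per grid mu required")
        n = {len(c.h) for c in self.curves}
        if len(n) != 1:
            raise ValueError("calibration curves must share bin structure")


@dataclass
class RateEstimate:
    """A fitted rate with its correction ledger and error budget."""

    mu_raw: float
    mu_corrected: float
    corrections: dict = field(default_factory=dict)
    jackknife_se: float = float("nan")
    parameter_se: dict = field(default_factory=dict)

    @property
    def combined_se(self) -> float:
        return combine_uncertainty(self.jackknife_se, *self.parameter_se.values())

    def to_dict(self) -> dict:
        return {
            "mu_raw": self.mu_raw, "mu_corrected": self.mu_corrected,
            "corrections": dict(self.corrections),
            "jackknife_se": self.jackknife_se,
            "parameter_se": dict(self.parameter_se),
            "combined_se": self.combined_se,
        }


def fit_mu(
    observed: CurveValues | HSCurve,
    calib: CalibrationSet,
    variances: np.ndarray | None = None,
    *,
    interpolation: str = "linear",
    refine_tol: float = 1e-13,
) -> float:
    """Best-fit mu by variance-weighted least squares against the calibration set.

    ``variances`` are per-bin variances of the observed curve (its own
    leave-one-chromosome jackknife when an HSCurve is given).  Zero or
    missing variances are replaced by the minimum positive variance with
    a warning.  Raises "extrapolation" when the observed curve escapes
    the calibration envelope in more than half the bins.
    """
    if isinstance(observed, HSCurve):
        if variances is None:
            variances = observed.bin_variances()
        observed = observed.values()
    h_obs = observed.h
    n_bins = len(h_obs)
    if variances is None:
        variances = np.ones(n_bins)
    variances = np.asarray(variances, dtype=float).copy()
    bad = ~(variances > 0) | ~np.isfinite(variances)
    if bad.all():
        variances[:] = 1.0
    elif bad.any():
        warnings.warn(f"{bad.sum()} degenerate bin variances replaced by minimum")
        variances[bad] = variances[~bad].min()
    weights = 1.0 / variances

    H = np.array([c.h for c in calib.curves])  # (n_grid, n_bins)
    # one-sided escape from the envelope signals extrapolation; symmetric
    # excursions are bin noise
    below = (h_obs < H.min(axis=0)).sum()
    above = (h_obs > H.max(axis=0)).sum()
    if max(below, above) > n_bins / 2:
        raise ValueError(
            "extrapolation: observed curve outside the calibration envelope "
            f"on one side in {max(below, above)}/{n_bins} bins")

    mu_grid = np.asarray(calib.mu_grid, dtype=float)
    # The curve family is close to linear in 1/mu (curve height tracks the
    # starting-point TMRCA, which scales as 1/mu at fixed theta), so the
    # per-bin interpolation runs over x = 1/mu; in linear mu the family is
    # convex and a sparse geometric grid would misplace interior members.
    order = np.argsort(1.0 / mu_grid)
    x_grid = (1.0 / mu_grid)[order]
    H_x = H[order]
    if interpolation == "spline":
        spl = CubicSpline(x_grid, H_x, axis=0, bc_type="not-a-knot")
        def family(x):
            return np.atleast_2d(spl(np.atleast_1d(x)))
    elif interpolation == "linear":
        def family(x):
            # piecewise linear in x = 1/mu, extended linearly beyond the
            # grid so fits just outside the envelope remain well defined
            x = np.atleast_1d(np.asarray(x, dtype=float))
            i = np.clip(np.searchsorted(x_grid, x) - 1, 0, len(x_grid) - 2)
            t = (x - x_grid[i]) / (x_grid[i + 1] - x_grid[i])
            return np.maximum(H_x[i] + t[:, None] * (H_x[i + 1] - H_x[i]), 0.0)
    else:
        raise ValueError("interpolation must be 'linear' or 'spline'")

    lo, hi = 0.5 * mu_grid.min(), 2.0 * mu_grid.max()
    dense = np.geomspace(lo, hi, 512)

    def objective(mu):
        resid = h_obs - family(np.atleast_1d(1.0 / mu))[0]
        return float(np.sum(weights * resid ** 2))

    vals = np.sum(weights * (h_obs - family(1.0 / dense)) ** 2, axis=-1)
    k = int(np.argmin(vals))
    bl = dense[max(k - 1, 0)]
    bh = dense[min(k + 1, len(dense) - 1)]
    res = minimize_scalar(objective, bounds=(bl, bh), method="bounded",
                          options={"xatol": refine_tol})
    return float(res.x)


def smooth_variances(variances: np.ndarray, window: int = 9) -> np.ndarray:
    """Moving geometric-mean smoothing of per-bin variances.

    Empirical per-bin variances are themselves noisy and, for a ratio
    statistic, correlate with the bin's own level fluctuation; using them
    raw as weights preferentially trusts downward-fluctuating bins and
    biases the fit upward when counts per bin are small.  Smoothing in
    log space across neighbouring bins keeps the overall variance profile
    (variance grows with the curve level) while decoupling each bin's
    weight from its own noise.
    """
    v = np.asarray(variances, dtype=float).copy()
    bad = ~(v > 0) | ~np.isfinite(v)
    if bad.all():
        return np.ones_like(v)
    if bad.any():
        v[bad] = v[~bad].min()
    logv = np.log(v)
    half = window // 2
    out = np.empty_like(logv)
    for i in range(len(v)):
        lo, hi = max(0, i - half), min(len(v), i + half + 1)
        out[i] = logv[lo:hi].mean()
    return np.exp(out)


def average_calibrations(fits) -> float:
    """Point estimate: mean over independently seeded calibration replicates."""
    fits = np.asarray(list(fits), dtype=float)
    if fits.size < 1:
        raise ValueError("need at least one calibration fit")
    return float(fits.mean())


def weighted_jackknife(full: float, loo: np.ndarray, weights: np.ndarray) -> float:
    """Weighted delete-one jackknife standard error.

    ``loo[j]`` is the estimate with block j removed, ``weights[j]`` the
    block's size (e.g. starting points per chromosome).  Uses the
    weighted-block formula standard in genome-wide resampling; with equal
    weights it reduces to the ordinary delete-one jackknife.
    """
    loo = np.asarray(loo, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(loo) < 2 or len(loo) != len(w):
        raise ValueError("need >= 2 leave-one-out estimates with matching weights")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    m = w.sum()
    g = len(loo)
    h = m / w
    if np.any(h <= 1):
        raise ValueError("a single block carries all the weight")
    theta_dot = g * full - np.sum((1.0 - w / m) * loo)  # jackknife mean
    tau = h * full - (h - 1.0) * loo                    # pseudovalues
    var = np.sum((tau - theta_dot) ** 2 / (h - 1.0)) / g
    return float(np.sqrt(var))


def propagate_alpha_uncertainty(fit_at_alpha, alpha_grid, alpha_se: float):
    """SE contribution of map-accuracy uncertainty.

    Reruns inference at each alpha in ``alpha_grid`` (callable
    ``fit_at_alpha(alpha) -> mu``), regresses mu on alpha, and returns
    ``(|slope| * alpha_se, fits)``.
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.size < 3:
        raise ValueError("need >= 3 alpha grid values")
    fits = np.array([fit_at_alpha(a) for a in alpha_grid])
    slope = linregress(alpha_grid, fits).slope
    return abs(slope) * alpha_se, fits


def combine_uncertainty(*components) -> float:
    """Root-sum-of-squares of independent normal error components."""
    comps = np.asarray([c for c in components if c is not None], dtype=float)
    comps = comps[np.isfinite(comps)]
    return float(np.sqrt(np.sum(comps ** 2)))


def per_year_rate(mu: float, generation_interval: float = 29.0) -> float:
    """Per-base per-year rate assuming a mean generation interval in years."""
    if generation_interval <= 0:
        raise ValueError("generation interval must be > 0")
    return mu / generation_interval


def tmrca_of_het(h: float, mu: float) -> float:
    """TMRCA (generations) implied by heterozygosity h: T = h / (2*mu)."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return h / (2.0 * mu)
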