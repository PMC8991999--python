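"""Mass-univariate association engine.

All feature-phenotype Pearson correlations with t-based two-tailed
p-values, bootstrap resampling over logarithmically spaced sample-size
bins (the default grid is the 16-bin schedule n = 25 ... 3,928 used for
univariate resampling in the reference study, with 1,000 draws per bin at
full scale and 200 at desk scale), and per-bin sampling-variability
interval summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UNIVARIATE_BINS",
    "ResamplingGrid",
    "ResamplingResult",
    "mass_correlate",
    "resample_bins",
    "variability_summary",
    "default_grid",
]

#: The 16 logarithmically spaced univariate resampling bins (full sample last).
UNIVARIATE_BINS = (
    25, 33, 50, 70, 100, 135, 200, 265, 375, 525, 725, 1000, 1430, 2000, 2800, 3928,
)


@dataclass(frozen=True)
class ResamplingGrid:
    """Ordered sample-size bins, iterations per bin, and a seed."""

    bins: tuple = UNIVARIATE_BINS
    B: int = 200
    seed: int = 0

    def __post_init__(self):
        b = tuple(self.bins)
        object.__setattr__(self, "bins", b)
        if len(b) == 0 or any(x >= y for x, y in zip(b, b[1:])):
            raise ValueError("bins must be non-empty and strictly increasing")
        if b[0] < 4:
            raise ValueError("smallest bin must be >= 4")
        if self.B < 1:
            raise ValueError("B must be >= 1")


def default_grid(population_size: int, B: int = 200, seed: int = 0) -> ResamplingGrid:
    """The canonical grid truncated at the population size (which becomes
    the last bin, sampled with replacement like every other bin)."""
    bins = tuple(b for b in UNIVARIATE_BINS if b < population_size) + (population_size,)
    return ResamplingGrid(bins=bins, B=B, seed=seed)


@dataclass
class ResamplingResult:
    """Correlation estimates and p-values per (feature, bin, iteration).

    Degenerate bootstrap draws (constant phenotype at tiny n) are recorded
    as NaN, never redrawn.
    """

    estimates: np.ndarray  # p x n_bins x B
    pvalues: np.ndarray
    bins: tuple
    full_sample_r: np.ndarray
    full_sample_p: np.ndarray
    n_full: int

    @property
    def n_features(self) -> int:
        return self.estimates.shape[0]


def mass_correlate(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of every column of ``X`` with ``y`` and two-tailed p-values.

    p-values come from ``t = r sqrt((n-2)/(1-r^2))`` on ``n - 2`` degrees of
    freedom.  Constant feature columns are flagged with NaN (r undefined),
    never silently zero; a constant ``y`` is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 4:
        raise ValueError("need n >= 4 observations")
    if y.shape[0] != n:
        raise ValueError("X and y length mismatch")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    if np.ptp(y) == 0.0:
        raise ValueError("phenotype is constant")
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    Xc = X - X.mean(axis=0)
    ss_x = np.einsum("ij,ij->j", Xc, Xc)
    constant = np.ptp(X, axis=0) == 0.0
    ss_x[constant] = np.nan  # constant feature sentinel, not silent zero
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / np.sqrt(ss_x * ss_y)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    p[np.isnan(r)] = np.nan
    return r, p


def resample_bins(
    X: np.ndarray,
    y: np.ndarray,
    grid: ResamplingGrid,
    dtype=np.float64,
) -> ResamplingResult:
    """Bootstrap the mass correlation over the grid.

    Every bin — including the full-sample bin — draws participants *with
    replacement* from the full population, so the largest bin is a
    bootstrap, not the identity.  Deterministic given ``grid.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if grid.bins[-1] > n:
        raise ValueError("largest bin exceeds population size")
    full_r, full_p = mass_correlate(X, y)
    est = np.full((p, len(grid.bins), grid.B), np.nan, dtype=dtype)
    pvs = np.full_like(est, np.nan)
    for bi, nb in enumerate(grid.bins):
        rng = np.random.default_rng([grid.seed, bi])
        for it in range(grid.B):
            idx = rng.integers(0, n, size=nb)
            ys = y[idx]
            if np.ptp(ys) == 0.0:
                continue  # degenerate draw: leave NaN
            r, pv = mass_correlate(X[idx], ys)
            est[:, bi, it] = r
            pvs[:, bi, it] = pv
    return ResamplingResult(
        estimates=est,
        pvalues=pvs,
        bins=grid.bins,
        full_sample_r=full_r,
        full_sample_p=full_p,
        n_full=n,
    )


def variability_summary(
    res: ResamplingResult,
    feature: int,
    levels: Iterable[float] = (95.0, 99.0),
) -> pd.DataFrame:
    """Per-bin sampling-variability intervals for one feature.

    Rows are bins; columns hold min/max and, for each confidence level,
    the empirical central interval bounds and its half-width
    (e.g. level 99 -> the (0.5, 99.5) percentiles).
    """
    if not 0 <= feature < res.n_features:
        raise ValueError("feature index out of range")
    rows = []
    for bi, nb in enumerate(res.bins):
        vals = res.estimates[feature, bi]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"no valid iterations for bin {nb}")
        row = {
            "bin": nb,
            "n_iterations": vals.size,
            "mean": vals.mean(),
            "min": vals.min(),
            "max": vals.max(),
        }
        for lev in levels:
            tail = (100.0 - lev) / 2.0
            lo, hi = np.percentile(vals, [tail, 100.0 - tail])
            row[f"lo{lev:g}"] = lo
            row[f"hi{lev:g}"] = hi
            row[f"halfwidth{lev:g}"] = (hi - lo) / 2.0
        rows.append(row)
    return pd.DataFrame(rows)
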