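"""Statistical-error calculus relative to full-sample ground truth.

False negatives, false positives, sign errors, effect-size inflation
(winner's curse), power, and discovery-to-replication rates, across a grid
of significance thresholds (P < 0.05 down to the Bonferroni-style 1e-7).
"Ground truth" is the realized full-sample result, mirroring a design in
which the full cohort defines which associations are real; rates against
the generator's true effects are additionally available for synthetic
populations, a capability real data lacks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthpop import SplitAssignment
from .univariate import ResamplingGrid, ResamplingResult, mass_correlate

__all__ = [
    "DEFAULT_ALPHAS",
    "AlphaGrid",
    "ErrorRateTable",
    "ground_truth_masks",
    "error_rates",
    "inflation_rates",
    "replication_rate",
]

DEFAULT_ALPHAS = (0.05, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7)


@dataclass(frozen=True)
class AlphaGrid:
    """Strictly decreasing two-tailed significance thresholds in (0, 1)."""

    alphas: tuple = DEFAULT_ALPHAS

    def __post_init__(self):
        a = tuple(self.alphas)
        object.__setattr__(self, "alphas", a)
        if len(a) == 0 or any(not 0 < x < 1 for x in a):
            raise ValueError("alphas must lie in (0, 1)")
        if any(x <= y for x, y in zip(a, a[1:])):
            raise ValueError("alphas must be strictly decreasing")

    def __iter__(self):
        return iter(self.alphas)

    def __len__(self):
        return len(self.alphas)


@dataclass
class ErrorRateTable:
    """Long-format rates indexed by (metric, bin, alpha).

    Empty eligible sets yield NaN rates (explicitly missing, never 0).
    """

    table: pd.DataFrame

    def rate(self, metric: str, bin: int, alpha: float) -> float:
        t = self.table
        row = t[(t.metric == metric) & (t.bin == bin) & (np.isclose(t.alpha, alpha))]
        if row.empty:
            raise KeyError((metric, bin, alpha))
        return float(row.rate.iloc[0])

    def pivot(self, metric: str) -> pd.DataFrame:
        t = self.table[self.table.metric == metric]
        return t.pivot(index="bin", columns="alpha", values="rate")


def _as_alphas(alphas) -> tuple:
    if isinstance(alphas, AlphaGrid):
        return alphas.alphas
    return AlphaGrid(tuple(alphas)).alphas


def ground_truth_masks(full_sample_p: np.ndarray, alphas) -> np.ndarray:
    """Boolean significance mask per alpha (n_alphas x p); masks are nested
    (stricter is a subset of looser)."""
    p = np.asarray(full_sample_p, dtype=float)
    alphas = _as_alphas(alphas)
    return np.stack([p < a for a in alphas])


def error_rates(res: ResamplingResult, masks: np.ndarray, alphas) -> ErrorRateTable:
    """Per (bin, alpha): FN, FP, sign-error and power rates.

    FN pools (feature, iteration) cells over full-sample-significant
    features; FP over non-significant ones; sign errors are the fraction of
    subsample-significant cells whose sign opposes the full sample; power
    is 1 - FN identically.
    """
    alphas = _as_alphas(alphas)
    masks = np.asarray(masks, dtype=bool)
    if masks.shape != (len(alphas), res.n_features):
        raise ValueError("masks shape must be (n_alphas, n_features)")
    sign_full = np.sign(res.full_sample_r)  # p
    rows = []
    for bi, nb in enumerate(res.bins):
        est = res.estimates[:, bi, :]  # p x B
        pv = res.pvalues[:, bi, :]
        valid = ~np.isnan(est)
        for ai, alpha in enumerate(alphas):
            sig_sub = (pv < alpha) & valid
            m = masks[ai]
            # False negatives / power over full-sample-significant features.
            n_fn_elig = int(valid[m].sum())
            if n_fn_elig:
                fn = float((~sig_sub[m] & valid[m]).sum() / n_fn_elig)
            else:
                fn = np.nan
            rows.append(dict(metric="FN", bin=nb, alpha=alpha, rate=fn,
                             n_eligible=n_fn_elig))
            rows.append(dict(metric="power", bin=nb, alpha=alpha,
                             rate=1.0 - fn if n_fn_elig else np.nan,
                             n_eligible=n_fn_elig))
            # False positives over non-significant features.
            n_fp_elig = int(valid[~m].sum())
            fp = float(sig_sub[~m].sum() / n_fp_elig) if n_fp_elig else np.nan
            rows.append(dict(metric="FP", bin=nb, alpha=alpha, rate=fp,
                             n_eligible=n_fp_elig))
            # Sign errors among subsample-significant cells.
            n_sig = int(sig_sub.sum())
            if n_sig:
                opp = np.sign(est) != sign_full[:, None]
                sgn = float((sig_sub & opp).sum() / n_sig)
            else:
                sgn = np.nan
            rows.append(dict(metric="sign", bin=nb, alpha=alpha, rate=sgn,
                             n_eligible=n_sig))
    return ErrorRateTable(pd.DataFrame(rows))


def inflation_rates(
    res: ResamplingResult,
    masks: np.ndarray,
    alphas,
    magnitudes: Sequence[float] = (0.5, 1.0, 2.0),
) -> ErrorRateTable:
    """Winner's-curse inflation among significant subsample estimates.

    For full-sample-significant features, among subsample-significant,
    same-sign iterations, the fraction whose magnitude exceeds the full
    sample by at least each relative magnitude (default 50/100/200%).
    Opposite-sign significant iterations are sign errors, not inflation.
    """
    alphas = _as_alphas(alphas)
    if any(m <= 0 for m in magnitudes):
        raise ValueError("magnitudes must be positive")
    masks = np.asarray(masks, dtype=bool)
    sign_full = np.sign(res.full_sample_r)
    abs_full = np.abs(res.full_sample_r)
    rows = []
    for bi, nb in enumerate(res.bins):
        est = res.estimates[:, bi, :]
        pv = res.pvalues[:, bi, :]
        valid = ~np.isnan(est)
        for ai, alpha in enumerate(alphas):
            m = masks[ai]
            elig = (pv < alpha) & valid & m[:, None]
            elig &= np.sign(est) == sign_full[:, None]
            n_elig = int(elig.sum())
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(est) / abs_full[:, None] - 1.0
            for mag in magnitudes:
                if n_elig:
                    rate = float((elig & (rel >= mag)).sum() / n_elig)
                else:
                    rate = np.nan
                rows.append(dict(metric=f"inflation_{int(round(mag * 100))}",
                                 bin=nb, alpha=alpha, rate=rate,
                                 n_eligible=n_elig))
    return ErrorRateTable(pd.DataFrame(rows))


def replication_rate(
    X: np.ndarray,
    y: np.ndarray,
    split: SplitAssignment,
    grid: ResamplingGrid,
    alphas,
    require_sign_match: bool = True,
) -> pd.DataFrame:
    """Probability that a discovery-significant association replicates.

    For each bin, ``grid.B`` bootstrap draws of that size are taken from
    the discovery half; associations significant in the draw are checked
    against the *full* replication half at the same alpha (identical
    thresholding in discovery and replication).  The denominator is the
    number of discovery-significant associations, pooled over features and
    iterations.  Both the sign-matched rate ("same sign, both significant")
    and the significance-only rate are reported; ``rate`` aliases the one
    selected by ``require_sign_match``.
    """
    alphas = _as_alphas(alphas)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Xd, yd = X[split.discovery_ids], y[split.discovery_ids]
    Xr, yr = X[split.replication_ids], y[split.replication_ids]
    if grid.bins[-1] > Xd.shape[0]:
        raise ValueError("largest bin exceeds the discovery-half size")
    rep_r, rep_p = mass_correlate(Xr, yr)
    rep_sig = {a: rep_p < a for a in alphas}
    n_disc = Xd.shape[0]
    rows = []
    for bi, nb in enumerate(grid.bins):
        rng = np.random.default_rng([grid.seed, bi])
        n_discovered = dict.fromkeys(alphas, 0)
        n_rep = dict.fromkeys(alphas, 0)
        n_rep_sign = dict.fromkeys(alphas, 0)
        for it in range(grid.B):
            idx = rng.integers(0, n_disc, size=nb)
            ys = yd[idx]
            if np.ptp(ys) == 0.0:
                continue
            dr, dp = mass_correlate(Xd[idx], ys)
            for a in alphas:
                disc = dp < a
                n_discovered[a] += int(disc.sum())
                both = disc & rep_sig[a]
                n_rep[a] += int(both.sum())
                n_rep_sign[a] += int((both & (np.sign(dr) == np.sign(rep_r))).sum())
        for a in alphas:
            d = n_discovered[a]
            r_any = n_rep[a] / d if d else np.nan
            r_sgn = n_rep_sign[a] / d if d else np.nan
            rows.append(dict(
                bin=nb, alpha=a, n_discoveries=d,
                rate_both_sig=r_any, rate_both_sig_same_sign=r_sgn,
                rate=r_sgn if require_sign_match else r_any,
            ))
    return pd.DataFrame(rows)
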