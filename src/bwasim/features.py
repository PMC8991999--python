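"""Connectome-style feature handling.

Correlation matrices from ROI timeseries (with frame censoring), the Fisher
z transform, canonical edge vectorization (strict upper triangle, row-major,
0-based — 394 ROIs give 77,421 edges), within/between network-block
averaging (14 networks give 105 blocks), and leakage-safe PCA reduction
where projection of held-out data uses training means and loadings only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "NetworkPartition",
    "PcaModel",
    "corrmat_from_timeseries",
    "fisher_z",
    "inverse_fisher",
    "vectorize_edges",
    "edges_to_matrix",
    "network_block_average",
    "pca_fit",
    "pca_project",
    "n_edges",
]

#: Cap applied to |r| = 1 when fisher_z(..., cap=True): atanh(1 - 1e-7).
FISHER_CAP_R = 1.0 - 1e-7


def n_edges(p_roi: int) -> int:
    """Number of unique ROI-ROI edges: p(p-1)/2."""
    if p_roi < 2:
        raise ValueError("need at least 2 ROIs")
    return p_roi * (p_roi - 1) // 2


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI matrix of Fisher-z edges; diagonal excluded
    from all downstream vectors."""

    values: np.ndarray
    roi_labels: Optional[Sequence[str]] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        self.values = v

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of every ROI to exactly one network label."""

    labels: tuple

    @property
    def n_networks(self) -> int:
        return len(set(self.labels))

    @property
    def n_blocks(self) -> int:
        k = self.n_networks
        return k * (k + 1) // 2


def fisher_z(r, cap: bool = False):
    """Variance-stabilizing ``z = atanh(r)``.

    ``|r| >= 1`` raises by default; ``cap=True`` clamps to ``1 - 1e-7``
    first (for user-supplied data where identical series can occur).
    """
    r = np.asarray(r, dtype=float)
    if cap:
        r = np.clip(r, -FISHER_CAP_R, FISHER_CAP_R)
    elif np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| >= 1 has infinite Fisher z; pass cap=True to clamp")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher(z):
    """Inverse transform ``r = tanh(z)``."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def corrmat_from_timeseries(
    ts: np.ndarray,
    keep_mask: Optional[np.ndarray] = None,
    min_frames: int = 600,
    cap: bool = False,
) -> ConnectivityMatrix:
    """Pearson correlations over retained frames, Fisher z-transformed.

    ``keep_mask`` abstracts motion censoring (True = retained frame);
    ``min_frames`` (default 600, i.e. 8 min at a 0.8 s repetition time)
    is the minimum number of retained frames.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be frames x ROIs")
    if keep_mask is not None:
        keep_mask = np.asarray(keep_mask, dtype=bool)
        if keep_mask.shape[0] != ts.shape[0]:
            raise ValueError("keep_mask length must match frame count")
        ts = ts[keep_mask]
    if ts.shape[0] < min_frames:
        raise ValueError(
            f"only {ts.shape[0]} retained frames; need at least {min_frames}"
        )
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance ROI(s) {bad.tolist()} after censoring")
    r = np.corrcoef(ts, rowvar=False)
    # Diagonal is exactly 1; zero it before the transform (it is excluded
    # downstream anyway) so only genuine |r| = 1 edges can trip the cap rule.
    off = r.copy()
    np.fill_diagonal(off, 0.0)
    # Colinear series can round to just under 1; treat them as |r| = 1.
    if not cap and np.any(np.abs(off) >= 1.0 - 1e-12):
        raise ValueError(
            "perfectly (anti)correlated ROI pair: Fisher z is infinite; "
            "pass cap=True to clamp"
        )
    zmat = fisher_z(off, cap=cap)
    np.fill_diagonal(zmat, 0.0)
    return ConnectivityMatrix(values=(zmat + zmat.T) / 2.0)


def vectorize_edges(m: ConnectivityMatrix | np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Strict upper triangle in row-major order (the canonical edge dialect)."""
    v = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(v, v.T, atol=atol):
        raise ValueError("input must be symmetric")
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def edges_to_matrix(edges: np.ndarray, p_roi: int) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`; zero diagonal."""
    edges = np.asarray(edges, dtype=float)
    if edges.shape[0] != n_edges(p_roi):
        raise ValueError("edge vector length does not match p(p-1)/2")
    out = np.zeros((p_roi, p_roi))
    iu = np.triu_indices(p_roi, k=1)
    out[iu] = edges
    return out + out.T


def network_block_average(
    m: ConnectivityMatrix | np.ndarray, part: NetworkPartition
) -> tuple[np.ndarray, list[tuple]]:
    """Mean edge value per unordered network pair (self-pairs included).

    Returns ``(values, block_labels)`` with ``k(k+1)/2`` entries for ``k``
    networks; within-network blocks average off-diagonal entries only.
    """
    v = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
    labels = np.asarray(part.labels)
    if labels.shape[0] != v.shape[0]:
        raise ValueError("partition must cover all ROIs")
    nets = sorted(set(labels.tolist()))
    idx = {net: np.flatnonzero(labels == net) for net in nets}
    for net in nets:
        if idx[net].size == 0:
            raise ValueError(f"empty network {net!r}")
    vals, names = [], []
    for i, a in enumerate(nets):
        for b in nets[i:]:
            ia, ib = idx[a], idx[b]
            block = v[np.ix_(ia, ib)]
            if a == b:
                if ia.size < 2:
                    raise ValueError(
                        f"network {a!r} has a single ROI; no off-diagonal entries"
                    )
                mask = ~np.eye(ia.size, dtype=bool)
                vals.append(block[mask].mean())
            else:
                vals.append(block.mean())
            names.append((a, b))
    return np.asarray(vals), names


@dataclass
class PcaModel:
    """PCA fitted on a discovery/training set only.

    ``loadings`` is feature x component with components ordered by
    decreasing variance; the retained set is the smallest prefix whose
    cumulative explained-variance fraction reaches ``variance_threshold``.
    Sign convention: each loading vector's largest-magnitude element is
    positive.
    """

    mean: np.ndarray
    loadings: np.ndarray
    component_variances: np.ndarray
    variance_threshold: float
    fitted_on: Optional[str] = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def pca_fit(
    X_train: np.ndarray,
    variance_threshold: float,
    fitted_on: Optional[str] = None,
    max_components: Optional[int] = None,
) -> PcaModel:
    """Fit PCA on training data and retain the smallest prefix of
    components reaching the cumulative variance threshold."""
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must lie in (0, 1]")
    X_train = np.asarray(X_train, dtype=float)
    n = X_train.shape[0]
    mean = X_train.mean(axis=0)
    Xc = X_train - mean
    # Economy SVD: component variances are s^2 / (n - 1).
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / max(n - 1, 1)
    total = var.sum()
    if total == 0:
        raise ValueError("training data has zero variance")
    frac = np.cumsum(var) / total
    k = int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)
    k = min(k, var.shape[0])
    if max_components is not None:
        if max_components < 1:
            raise ValueError("max_components must be >= 1")
        k = min(k, max_components)
    load = Vt[:k].T.copy()
    # Deterministic sign: largest-|element| of each loading vector positive.
    flip = np.sign(load[np.abs(load).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    load *= flip
    return PcaModel(
        mean=mean,
        loadings=load,
        component_variances=var[:k],
        variance_threshold=variance_threshold,
        fitted_on=fitted_on,
    )


def pca_project(model: PcaModel, X: np.ndarray) -> np.ndarray:
    """Project any data through training means and loadings (no leakage)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError("feature dimension mismatch")
    return (X - model.mean) @ model.loadings
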