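"""Old-vs-young transcriptomic divergence per cell type.

Each cell type's two group clouds are compared in a reduced principal-
component space with the Bhattacharyya distance under a Gaussian
approximation:

    D = 1/8 (mu1 - mu2)' S^-1 (mu1 - mu2)
        + 1/2 ln( det S / sqrt(det S1 det S2) ),   S = (S1 + S2) / 2

The first term captures mean separation, the second covariance mismatch;
D = 0 iff the two Gaussians coincide.  To de-bias for unequal group
sizes, a fixed number of cells per group (default 250) is subsampled and
the distance recomputed over repetitions (default 100); cell types are
ranked by the median of the repetition distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core_io import NormMatrix

__all__ = [
    "embed_pca",
    "bhattacharyya_gaussian",
    "subsampled_divergence",
    "DivergenceResult",
]


def embed_pca(norm: NormMatrix, dims: int = 10, n_hvg: int = 2000) -> pd.DataFrame:
    """PCA embedding on centered, unit-scaled highly-variable genes.

    The top ``n_hvg`` genes by variance enter the decomposition (all
    genes when fewer are available).  Component signs are fixed by making
    each component's largest-magnitude loading positive, so the embedding
    is deterministic.
    """
    X = norm.values
    if X.shape[1] < dims:
        raise ValueError(f"{X.shape[1]} genes < requested dims={dims}")
    if X.shape[0] < dims + 1:
        raise ValueError(f"{X.shape[0]} observations too few for dims={dims}")
    var = X.var(axis=0)
    if X.shape[1] > n_hvg:
        keep = np.argsort(-var, kind="stable")[:n_hvg]
        keep.sort()
        X = X[:, keep]
        var = var[keep]
    sd = np.sqrt(var)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd

    pca = PCA(n_components=dims, svd_solver="full")
    coords = pca.fit_transform(Xs)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(dims):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            coords[:, k] *= -1
    return pd.DataFrame(coords, index=norm.obs_ids,
                        columns=[f"PC{i + 1}" for i in range(dims)])


def bhattacharyya_gaussian(X1: np.ndarray, X2: np.ndarray,
                           ridge: float = 1e-6) -> float:
    """Closed-form Bhattacharyya distance between two Gaussian fits.

    ``ridge * I`` is added to each sample covariance for numerical
    stability at moderate n.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.ndim == 2 and X1.shape[1] != X2.shape[1]:
        raise ValueError("dimension mismatch")
    d = X1.shape[1]
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    S1 = np.cov(X1, rowvar=False).reshape(d, d) + ridge * np.eye(d)
    S2 = np.cov(X2, rowvar=False).reshape(d, d) + ridge * np.eye(d)
    S = 0.5 * (S1 + S2)
    diff = mu1 - mu2
    term_mean = 0.125 * diff @ np.linalg.solve(S, diff)
    sign, logdet_s = np.linalg.slogdet(S)
    s1sign, logdet_1 = np.linalg.slogdet(S1)
    s2sign, logdet_2 = np.linalg.slogdet(S2)
    if min(sign, s1sign, s2sign) <= 0:
        raise ValueError("covariance not positive definite even after ridge")
    term_cov = 0.5 * (logdet_s - 0.5 * (logdet_1 + logdet_2))
    D = float(term_mean + term_cov)
    if not np.isfinite(D):
        raise ValueError("non-finite Bhattacharyya distance")
    return D


@dataclass
class DivergenceResult:
    """Per-type repetition distances plus the parameters that produced them."""

    distances: pd.DataFrame            # reps x cell types
    n_per_group: int
    reps: int
    dims: int
    with_replacement: dict[str, bool] = field(default_factory=dict)

    @property
    def median(self) -> pd.Series:
        return self.distances.median(axis=0).sort_values(ascending=False)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "median": self.distances.median(axis=0),
            "mean": self.distances.mean(axis=0),
            "q25": self.distances.quantile(0.25, axis=0),
            "q75": self.distances.quantile(0.75, axis=0),
        }).sort_values("median", ascending=False)
        out["rank"] = np.arange(1, len(out) + 1)
        out["with_replacement"] = [self.with_replacement.get(t, False)
                                   for t in out.index]
        return out


def subsampled_divergence(embedding: pd.DataFrame, meta: pd.DataFrame,
                          n_per_group: int = 250, reps: int = 100,
                          seed: int = 0, ridge: float = 1e-6) -> DivergenceResult:
    """Repeated subsampled Bhattacharyya distance per cell type.

    Per repetition, ``n_per_group`` cells per group are drawn without
    replacement (with replacement, flagged, when a group is smaller) and
    the Gaussian Bhattacharyya distance computed on their embedding
    coordinates.  Types with an empty group are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    meta = meta.set_index("obs_id").loc[embedding.index]
    dims = embedding.shape[1]
    coords = embedding.to_numpy()

    dist_cols: dict[str, np.ndarray] = {}
    with_repl: dict[str, bool] = {}
    for ct in sorted(meta["cell_type"].dropna().unique()):
        idx_old = np.flatnonzero((meta["cell_type"] == ct) & (meta["group"] == "old"))
        idx_young = np.flatnonzero((meta["cell_type"] == ct) & (meta["group"] == "young"))
        if len(idx_old) == 0 or len(idx_young) == 0:
            warnings.warn(f"cell type {ct!r} missing a group; skipped")
            continue
        repl = len(idx_old) < n_per_group or len(idx_young) < n_per_group
        if repl:
            warnings.warn(f"cell type {ct!r}: sampling with replacement "
                          f"(group sizes {len(idx_old)}/{len(idx_young)} < {n_per_group})")
        with_repl[ct] = repl
        ds = np.empty(reps)
        for r in range(reps):
            s_old = rng.choice(idx_old, size=n_per_group,
                               replace=len(idx_old) < n_per_group)
            s_young = rng.choice(idx_young, size=n_per_group,
                                 replace=len(idx_young) < n_per_group)
            ds[r] = bhattacharyya_gaussian(coords[s_old], coords[s_young], ridge=ridge)
        dist_cols[ct] = ds

    distances = pd.DataFrame(dist_cols)
    distances.index.name = "rep"
    return DivergenceResult(distances=distances, n_per_group=n_per_group,
                            reps=reps, dims=dims, with_replacement=with_repl)
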