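"""Spatial co-localization: layer density profiles, correlation analyses
and a within-sample permutation colocalization test.

The observed colocalization score of a cell-type pair is the Pearson
correlation of their per-spot densities computed within each sample and
averaged across samples.  Its null distribution is built by permuting one
type's densities across spots independently within each sample — which
preserves every per-sample density distribution while destroying spatial
pairing — and the one-sided permutation p-value uses the add-one rule
``p = (1 + #{null >= observed}) / (n_perm + 1)``, so it is never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "layer_profile",
    "density_correlation",
    "score_correlation",
    "permutation_coloc",
    "ColocResult",
    "LayerProfile",
]


def abundance_proportions(ab: pd.DataFrame) -> pd.DataFrame:
    """Per-spot cell-type proportions; all-zero rows stay all-zero."""
    totals = ab.sum(axis=1)
    out = ab.div(totals.where(totals > 0, 1.0), axis=0)
    return out


@dataclass
class LayerProfile:
    """Mean density/proportion per (cell type, sample, layer)."""

    density: pd.DataFrame      # rows: (sample_id, layer) MultiIndex, cols: types
    proportion: pd.DataFrame
    scaled_density: pd.DataFrame  # z-scored per cell type over the grid

    def long(self) -> pd.DataFrame:
        d = self.density.stack().rename("mean_density")
        p = self.proportion.stack().rename("mean_proportion")
        s = self.scaled_density.stack().rename("scaled_density")
        out = pd.concat([d, p, s], axis=1).reset_index()
        return out.rename(columns={"level_2": "cell_type"})


@dataclass
class ColocResult:
    pair: tuple[str, str]
    observed: float | None = None
    r: float | None = None
    p_r: float | None = None
    n_points: int | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    null_q95: float | None = None
    p_perm: float | None = None
    n_perm: int | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def layer_profile(ab: pd.DataFrame, zn: pd.DataFrame,
                  meta: pd.DataFrame) -> LayerProfile:
    """Aggregate spot abundances to (cell type, sample, layer) means.

    ``zn`` is the layer table from :func:`liverspatial.zonation.assign_layers`.
    The scaled variant z-scores each cell type's mean density across the
    full sample x layer grid (types with zero spread map to 0).
    """
    zn = zn.set_index("obs_id")
    missing = ab.index.difference(zn.index)
    if len(missing):
        raise ValueError(f"{len(missing)} spots in abundance matrix have no layer")
    keys = zn.loc[ab.index, ["sample_id", "layer"]]
    grouped = ab.groupby([keys["sample_id"], keys["layer"]])
    density = grouped.mean()
    proportion = abundance_proportions(ab).groupby(
        [keys["sample_id"], keys["layer"]]).mean()
    sd = density.std(axis=0, ddof=0)
    scaled = (density - density.mean(axis=0)).div(sd.where(sd > 0, 1.0), axis=1)
    return LayerProfile(density=density, proportion=proportion, scaled_density=scaled)


def density_correlation(profile: LayerProfile, focal: str, others: list[str],
                        mode: str = "density") -> list[ColocResult]:
    """Pearson correlation of the focal type's layer profile with others.

    Correlations run over the (sample, layer) grid of mean densities or
    proportions; two-sided p from the t distribution with n-2 df.
    """
    table = {"density": profile.density, "proportion": profile.proportion}[mode]
    if focal not in table.columns:
        raise KeyError(f"unknown focal type {focal!r}")
    x = table[focal].to_numpy()
    if len(x) < 3:
        raise ValueError("need >= 3 (sample, layer) points")
    out = []
    for other in others:
        y = table[other].to_numpy()
        res = ColocResult(pair=(focal, other), n_points=len(x))
        if np.std(x) == 0 or np.std(y) == 0:
            res.note = "zero-variance profile; correlation undefined"
        else:
            r, p = scipy.stats.pearsonr(x, y)
            res.r, res.p_r = float(r), float(p)
        out.append(res)
    return out


def score_correlation(scores: pd.DataFrame, sig_a: str, sig_b: str,
                      spots: pd.Index | None = None) -> ColocResult:
    """Per-spot Pearson correlation between two signature scores."""
    for name in (sig_a, sig_b):
        if name not in scores.columns:
            raise KeyError(f"signature {name!r} not scored")
    sub = scores if spots is None else scores.loc[spots]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 spots, got {len(sub)}")
    r, p = scipy.stats.pearsonr(sub[sig_a], sub[sig_b])
    return ColocResult(pair=(sig_a, sig_b), r=float(r), p_r=float(p),
                       n_points=len(sub))


def permutation_coloc(ab: pd.DataFrame, meta: pd.DataFrame, type_a: str,
                      type_b: str, n_perm: int = 10000, seed: int = 0,
                      stat: str = "pearson") -> ColocResult:
    """Permutation test of spatial co-localization of two cell types.

    Observed statistic: within-sample Pearson correlation of the per-spot
    densities of ``type_a`` and ``type_b``, averaged across samples (the
    mean observed colocalization score).  With ``stat='min_product'`` the
    statistic is instead the spot-mean of ``min(a, b)`` products after
    per-sample mean-scaling — a non-correlation overlap measure.  The
    null permutes ``type_b`` densities across spots within each sample.
    """
    for t in (type_a, type_b):
        if t not in ab.columns:
            raise KeyError(f"cell type {t!r} absent from abundance matrix")
    sample_of = meta.set_index("obs_id")["sample_id"]
    samples = sample_of.loc[ab.index]

    obs_parts, null_parts = [], []
    rng = np.random.default_rng(seed)
    kept = 0
    for sample, idx in ab.groupby(samples).groups.items():
        a = ab.loc[idx, type_a].to_numpy(dtype=float)
        b = ab.loc[idx, type_b].to_numpy(dtype=float)
        if len(a) < 3:
            warnings.warn(f"sample {sample!r} has < 3 spots; excluded")
            continue
        kept += 1
        if stat == "pearson":
            if a.std() == 0 or b.std() == 0:
                warnings.warn(f"sample {sample!r}: zero-variance density; excluded")
                kept -= 1
                continue
            az = (a - a.mean()) / a.std()
            bz = (b - b.mean()) / b.std()
            obs_parts.append(np.mean(az * bz))
            # permuted correlations, vectorized over all permutations
            perm = np.argsort(rng.random((n_perm, len(bz))), axis=1)
            null_parts.append((az[None, :] * bz[perm]).mean(axis=1))
        elif stat == "min_product":
            am = a / a.mean() if a.mean() > 0 else a
            bm = b / b.mean() if b.mean() > 0 else b
            obs_parts.append(np.mean(np.minimum(am, bm)))
            perm = np.argsort(rng.random((n_perm, len(bm))), axis=1)
            null_parts.append(np.minimum(am[None, :], bm[perm]).mean(axis=1))
        else:
            raise ValueError(f"unknown stat {stat!r}")
    if kept == 0:
        raise ValueError("no sample with enough spots")

    observed = float(np.mean(obs_parts))
    null = np.mean(null_parts, axis=0)
    p_perm = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return ColocResult(
        pair=(type_a, type_b), observed=observed,
        null_mean=float(null.mean()), null_sd=float(null.std()),
        null_q95=float(np.quantile(null, 0.95)),
        p_perm=float(p_perm), n_perm=n_perm,
    )
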