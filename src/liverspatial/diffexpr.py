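"""Two-group differential expression and the three-way DEG intersection.

Per gene, the fold-change is computed on de-logged normalized means,
``log2fc = log2((mean_a + eps) / (mean_b + eps))`` with ``eps = 1e-9``,
and significance from a two-sided Wilcoxon rank-sum test with
Benjamini-Hochberg adjustment across tested genes.  A gene is called
``up``/``down`` when ``|log2fc|`` clears the fold threshold AND the
adjusted p clears ``padj_thresh``; the conventional strict threshold is
``|log2fc| > 1``, the lenient one ``> 0.25``, both at adjusted p < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core_io import NormMatrix

__all__ = ["de_test", "deg_intersect"]

EPS = 1e-9


def de_test(norm: NormMatrix, meta: pd.DataFrame, group_a: str, group_b: str,
            lfc_thresh: float = 1.0, padj_thresh: float = 0.05,
            group_col: str = "group") -> pd.DataFrame:
    """Rank-sum differential expression of group_a vs group_b.

    Positive ``log2fc`` means higher in ``group_a``.  Returns a DataFrame
    with columns gene, log2fc, p, p_adj, pct_a, pct_b, direction.
    """
    labels = meta.set_index("obs_id").loc[norm.obs_ids, group_col]
    in_a = (labels == group_a).to_numpy()
    in_b = (labels == group_b).to_numpy()
    if in_a.sum() < 3 or in_b.sum() < 3:
        raise ValueError(
            f"groups too small: {group_a}={in_a.sum()}, {group_b}={in_b.sum()}"
        )
    Xa, Xb = norm.values[in_a], norm.values[in_b]
    mean_a = np.expm1(Xa).mean(axis=0)
    mean_b = np.expm1(Xb).mean(axis=0)
    log2fc = np.log2(mean_a + EPS) - np.log2(mean_b + EPS)

    res = scipy.stats.mannwhitneyu(Xa, Xb, axis=0, alternative="two-sided",
                                   method="asymptotic")
    p = np.asarray(res.pvalue)
    # constant genes yield undefined p under the rank test; treat as null
    p = np.where(np.isnan(p), 1.0, p)
    p_adj = multipletests(p, method="fdr_bh")[1]

    sig = (np.abs(log2fc) > lfc_thresh) & (p_adj < padj_thresh)
    direction = np.where(sig & (log2fc > 0), "up",
                         np.where(sig & (log2fc < 0), "down", "ns"))
    return pd.DataFrame({
        "gene": norm.gene_ids,
        "log2fc": log2fc,
        "p": p,
        "p_adj": p_adj,
        "pct_a": (Xa > 0).mean(axis=0),
        "pct_b": (Xb > 0).mean(axis=0),
        "direction": direction,
    })


def deg_intersect(results: list[pd.DataFrame]) -> tuple[set[str], set[str]]:
    """Genes consistently up (and down) across all DE comparisons."""
    if len(results) != 3:
        raise ValueError(f"expected exactly 3 DE results, got {len(results)}")
    ups = [set(r.loc[r["direction"] == "up", "gene"]) for r in results]
    downs = [set(r.loc[r["direction"] == "down", "gene"]) for r in results]
    return set.intersection(*ups), set.intersection(*downs)
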