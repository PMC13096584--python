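"""Cell-type composition analysis: proportions, fold-change ranking and
observed/expected (Ro/e) chi-square enrichment.

Ro/e for cell type X is the number of X cells observed in the old group
divided by the count expected under independence of type and group
(``old_total * type_total / grand_total``); values above 1 indicate
old-group enrichment.  Significance comes from a Pearson chi-square test
(df = 1, no continuity correction by default) on the 2x2 table
(X / not-X) x (old / young) built over an explicit cell universe.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = ["proportions", "log2fc_proportion", "roe_enrichment"]


def proportions(meta: pd.DataFrame, by: str = "sample") -> pd.DataFrame:
    """Cell-type proportions per sample (``by='sample'``) or group.

    Returns a unit x cell-type DataFrame whose rows sum to 1.
    """
    if "cell_type" not in meta.columns or meta["cell_type"].isna().all():
        raise ValueError("cell_type labels required")
    unit = {"sample": "sample_id", "group": "group"}[by]
    tab = pd.crosstab(meta[unit], meta["cell_type"])
    empty = tab.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"empty units excluded: {tab.index[empty].tolist()}")
        tab = tab.loc[~empty]
    return tab.div(tab.sum(axis=1), axis=0)


def log2fc_proportion(prop: pd.DataFrame, meta: pd.DataFrame,
                      pseudo: float = 1e-4) -> pd.DataFrame:
    """log2 of old-vs-young mean proportion per type, sorted descending.

    ``prop`` is the per-sample proportion table; group means are taken
    over samples (not pooled cells), then
    ``log2((mean_old + pseudo) / (mean_young + pseudo))``.
    """
    sample_group = meta.drop_duplicates("sample_id").set_index("sample_id")["group"]
    groups = prop.index.map(sample_group)
    for g in ("young", "old"):
        if (groups == g).sum() == 0:
            raise ValueError(f"no samples in group {g!r}")
    mean_old = prop[groups == "old"].mean(axis=0)
    mean_young = prop[groups == "young"].mean(axis=0)
    lfc = np.log2((mean_old + pseudo) / (mean_young + pseudo))
    out = pd.DataFrame({
        "mean_old": mean_old, "mean_young": mean_young, "log2fc": lfc,
    }).sort_values("log2fc", ascending=False)
    out.index.name = "cell_type"
    return out


def roe_enrichment(meta: pd.DataFrame, universe: list[str] | None = None,
                   yates: bool = False) -> pd.DataFrame:
    """Per-type Ro/e and chi-square over the stated cell universe.

    ``universe`` restricts the not-X complement (e.g. all immune types);
    it must be given explicitly when the metadata holds non-immune types
    that should not enter the denominators.  Per type, the 2x2 table
    (X / not-X) x (old / young) is tested with Pearson chi-square
    (Yates continuity correction off by default).  Alongside the per-type
    p-value a BH-adjusted column is emitted.  Expected cells below 1 set
    ``reliable=False`` but the values are still reported.
    """
    if universe is None:
        universe = sorted(meta["cell_type"].dropna().unique())
    sub = meta[meta["cell_type"].isin(universe)]
    for g in ("young", "old"):
        if (sub["group"] == g).sum() == 0:
            raise ValueError(f"group {g!r} empty within the universe")

    counts = pd.crosstab(sub["cell_type"], sub["group"])
    for g in ("young", "old"):
        if g not in counts.columns:
            counts[g] = 0
    old_total = int(counts["old"].sum())
    young_total = int(counts["young"].sum())
    grand = old_total + young_total

    rows = []
    for ct in universe:
        n_old_x = int(counts.loc[ct, "old"]) if ct in counts.index else 0
        n_young_x = int(counts.loc[ct, "young"]) if ct in counts.index else 0
        n_old_not = old_total - n_old_x
        n_young_not = young_total - n_young_x
        type_total = n_old_x + n_young_x
        expected_old_x = old_total * type_total / grand
        table = np.array([[n_old_x, n_old_not], [n_young_x, n_young_not]])
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, exp = scipy.stats.chi2_contingency(table, correction=yates)
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / max(grand, 1)
        rows.append({
            "cell_type": ct,
            "n_old_X": n_old_x, "n_young_X": n_young_x,
            "n_old_notX": n_old_not, "n_young_notX": n_young_not,
            "expected_old_X": expected_old_x,
            "roe": n_old_x / expected_old_x if expected_old_x > 0 else np.nan,
            "chi2": float(chi2), "p": float(p),
            "reliable": bool(expected.min() >= 1),
        })
    out = pd.DataFrame(rows).set_index("cell_type")
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
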