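"""Zonation scoring and per-sample layer allocation along the CV-PV axis.

Each spatial spot receives a region score — pericentral (CV) signature
score minus periportal (PV) signature score, so high values are CV-like —
and spots are then stratified, within each sample independently, into
``n_layers`` equal-count quantile bins of descending region score.
Layer 1 is the most CV-like, layer 9 the most PV-like; layers 1-3 are the
CV zone, 4-6 the intermediate zone, 7-9 the PV zone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["region_score", "assign_layers", "layer_zone"]

ZONE_OF_THIRD = ("CV", "mid", "PV")


def region_score(scores: pd.DataFrame, cv_sig: str, pv_sig: str) -> pd.Series:
    """CV signature score minus PV signature score, per spot."""
    for name in (cv_sig, pv_sig):
        if name not in scores.columns:
            raise KeyError(f"signature {name!r} not present in score table")
    out = scores[cv_sig] - scores[pv_sig]
    out.name = "region_score"
    return out


def layer_zone(layer: np.ndarray | pd.Series, n_layers: int = 9) -> np.ndarray:
    """Map layer number to zone label: first third CV, middle mid, last PV."""
    thirds = np.ceil(np.asarray(layer) * 3 / n_layers).astype(int) - 1
    return np.array(ZONE_OF_THIRD)[np.clip(thirds, 0, 2)]


def assign_layers(region_scores: pd.Series, meta: pd.DataFrame,
                  n_layers: int = 9) -> pd.DataFrame:
    """Per-sample equal-count stratification of spots by descending score.

    Within each sample, spots are sorted by region score descending (ties
    broken by obs_id, so assignment is deterministic) and split into
    ``n_layers`` contiguous blocks whose sizes differ by at most one;
    when the count is not divisible, the larger blocks take the lower
    layer numbers.  Returns a DataFrame with columns ``obs_id``,
    ``sample_id``, ``region_score``, ``layer``, ``zone``.
    """
    meta = meta.set_index("obs_id")
    missing = region_scores.index.difference(meta.index)
    if len(missing):
        raise KeyError(f"{len(missing)} scored spots absent from metadata")

    pieces = []
    samples = meta.loc[region_scores.index, "sample_id"]
    for sample, idx in region_scores.groupby(samples).groups.items():
        s = region_scores.loc[idx]
        n = len(s)
        if n < n_layers:
            raise ValueError(
                f"sample {sample!r} has {n} spots, fewer than {n_layers} layers"
            )
        order = np.lexsort((s.index.to_numpy(), -s.to_numpy()))
        base, rem = divmod(n, n_layers)
        layers = np.empty(n, dtype=int)
        start = 0
        for layer in range(1, n_layers + 1):
            size = base + (1 if layer <= rem else 0)
            layers[order[start: start + size]] = layer
            start += size
        pieces.append(pd.DataFrame({
            "obs_id": s.index,
            "sample_id": sample,
            "region_score": s.to_numpy(),
            "layer": layers,
        }))
    out = pd.concat(pieces, ignore_index=True)
    out["zone"] = layer_zone(out["layer"], n_layers)
    return out
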