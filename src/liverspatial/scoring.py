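"""Gene-signature (module) scoring and marker-signature construction.

The module score of a gene set on an observation is the mean normalized
expression of the set minus the mean of a pooled control set: genes are
binned into ``nbins`` equal-count groups by dataset-wide average
expression, and for each signature gene ``nctrl`` control genes are drawn
from its bin (without replacement within a bin, signature genes excluded;
bins may be re-drawn across signature genes).  Subtracting
expression-matched controls removes library-depth and overall-activity
gradients, so the score reflects coordinated up-regulation of the set —
the construction behind "AddModuleScore"-style scoring.

The six-gene exhaustion signature used throughout the analyses lives in
:data:`EXHAUSTION_SIGNATURE`.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_io import NormMatrix

__all__ = [
    "SignatureSet",
    "EXHAUSTION_SIGNATURE",
    "module_score",
    "score_all",
    "build_marker_signatures",
    "read_gmt",
    "write_gmt",
]

logger = logging.getLogger(__name__)

#: Canonical exhausted-CD8 T cell signature (murine symbols).
EXHAUSTION_SIGNATURE = ["Pdcd1", "Lag3", "Tigit", "Tox", "Havcr2", "Cxcl13"]


class SignatureSet(dict):
    """Named, ordered, non-empty gene lists; optionally mutually disjoint."""

    def __init__(self, sigs: dict[str, list[str]] | None = None,
                 mutually_disjoint: bool = False):
        super().__init__()
        self.mutually_disjoint = mutually_disjoint
        for name, genes in (sigs or {}).items():
            self[name] = list(genes)
        self.validate()

    def validate(self) -> None:
        for name, genes in self.items():
            if not genes:
                raise ValueError(f"signature {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"signature {name!r} contains duplicate genes")
        if self.mutually_disjoint:
            seen: dict[str, str] = {}
            for name, genes in self.items():
                for g in genes:
                    if g in seen:
                        raise ValueError(
                            f"gene {g!r} appears in both {seen[g]!r} and {name!r} "
                            "but the set is flagged mutually disjoint"
                        )
                    seen[g] = name


def read_gmt(path: str | Path) -> SignatureSet:
    sigs = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sigs[fields[0]] = [g for g in fields[2:] if g]
    return SignatureSet(sigs)


def write_gmt(sigs: SignatureSet, path: str | Path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(genes) for name, genes in sigs.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_signature_yaml(path: str | Path) -> SignatureSet:
    d = yaml.safe_load(Path(path).read_text())
    return SignatureSet({k: list(v) for k, v in d.items()})


def _expression_bins(avg: pd.Series, nbins: int) -> np.ndarray:
    """Equal-count bins of genes by average expression (ties by gene id)."""
    order = np.lexsort((avg.index.to_numpy(), avg.to_numpy()))
    n = len(avg)
    base, rem = divmod(n, nbins)
    bins = np.empty(n, dtype=int)
    start = 0
    for b in range(nbins):
        size = base + (1 if b < rem else 0)
        bins[order[start: start + size]] = b
        start += size
    return bins


def module_score(norm: NormMatrix, sig: list[str], nbins: int = 24,
                 nctrl: int = 100, seed: int | np.random.Generator = 0) -> pd.Series:
    """Expression-bin-matched control score of one gene set per observation."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = norm.gene_ids
    present = [g for g in sig if g in genes]
    missing = [g for g in sig if g not in genes]
    if missing:
        logger.warning("dropping %d signature genes absent from matrix: %s",
                       len(missing), missing[:10])
    if not present:
        raise ValueError(f"all signature genes absent from the matrix: {sig[:10]}")

    avg = pd.Series(norm.values.mean(axis=0), index=genes)
    bins = _expression_bins(avg, min(nbins, len(genes)))
    sig_idx = genes.get_indexer(present)
    sig_set = set(present)

    ctrl_cols: list[np.ndarray] = []
    gene_positions = np.arange(len(genes))
    for gi in sig_idx:
        pool = gene_positions[(bins == bins[gi])]
        pool = np.array([p for p in pool if genes[p] not in sig_set])
        if len(pool) == 0:
            continue
        take = min(nctrl, len(pool))
        ctrl_cols.append(rng.choice(pool, size=take, replace=False))
    if not ctrl_cols:
        raise ValueError("no control genes available outside the signature")
    ctrl_idx = np.concatenate(ctrl_cols)

    # center each observation on its first signature gene before averaging:
    # a mathematical no-op (both means shift equally) that keeps the score
    # exactly zero on observation-constant input
    ref = norm.values[:, sig_idx[0]][:, None]
    score = (norm.values[:, sig_idx] - ref).mean(axis=1) \
        - (norm.values[:, ctrl_idx] - ref).mean(axis=1)
    return pd.Series(score, index=norm.obs_ids, name="score")


def score_all(norm: NormMatrix, sigs: SignatureSet, nbins: int = 24,
              nctrl: int = 100, seed: int = 0) -> pd.DataFrame:
    """Score every signature; returns obs x signature DataFrame (ScoreTable)."""
    sigs.validate()
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(index=norm.obs_ids.copy())
    for name, genes in sigs.items():
        table[name] = module_score(norm, genes, nbins=nbins, nctrl=nctrl, seed=rng)
    return table


def build_marker_signatures(norm: NormMatrix, meta: pd.DataFrame,
                            level: str = "cell_type", top_n: int = 30,
                            min_cells: int = 3) -> SignatureSet:
    """Top-``top_n`` label-vs-rest marker genes per label, made disjoint.

    Genes are ranked within each label by one-vs-rest log2 fold-change
    (ties by adjusted p, then gene id).  A gene claimed by several labels
    is kept by the label with the larger fold-change (ties: lexicographic
    label order) and removed from the others, so the resulting set is
    mutually disjoint.
    """
    from .diffexpr import de_test  # single DE engine for the whole package

    meta = meta.set_index("obs_id").loc[norm.obs_ids]
    labels = meta[level]
    counts = labels.value_counts()
    usable = sorted(counts.index[counts >= min_cells])
    dropped = sorted(set(counts.index) - set(usable))
    if dropped:
        warnings.warn(f"labels with < {min_cells} observations excluded: {dropped}")
    if len(usable) < 2:
        raise ValueError("need >= 2 labels with enough observations")

    claims: dict[str, list[tuple[str, float]]] = {}
    ranked: dict[str, list[str]] = {}
    for lab in usable:
        in_lab = (labels == lab).to_numpy()
        res = de_test(norm, meta.assign(_grp=np.where(in_lab, "a", "b")).reset_index(),
                      group_a="a", group_b="b", group_col="_grp")
        res = res.sort_values(["log2fc", "p_adj", "gene"],
                              ascending=[False, True, True])
        top = res.head(top_n)
        ranked[lab] = top["gene"].tolist()
        for g, fc in zip(top["gene"], top["log2fc"]):
            claims.setdefault(g, []).append((lab, float(fc)))

    final: dict[str, list[str]] = {lab: [] for lab in usable}
    for lab in usable:
        for g in ranked[lab]:
            # ties by fold-change resolved toward the lexicographically first label
            best_fc = max(fc for _, fc in claims[g])
            winners = sorted(l for l, fc in claims[g] if fc == best_fc)
            if winners[0] == lab:
                final[lab].append(g)
    final = {lab: genes for lab, genes in final.items() if genes}
    return SignatureSet(final, mutually_disjoint=True)
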