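"""Core data containers, file I/O, quality control and normalization.

The analysis operates on three tabular objects:

``CountMatrix``
    Observations (cells or spatial spots) x genes, non-negative integer
    UMI counts, stored dense (the package targets matrices that fit in
    memory after gene filtering; MatrixMarket input is densified on read).

``ObsMeta``
    A :class:`pandas.DataFrame` with one row per observation and the
    columns ``obs_id`` (unique), ``sample_id``, ``group`` (``young`` /
    ``old``), and optionally ``cell_type``, ``x``, ``y`` (integer spot
    bin-center coordinates), ``layer`` and ``qc_pass``.

``NormMatrix``
    Same shape as the count matrix it came from; values are
    ``log(1 + count * scale / obs_total)`` (library-size normalization
    with natural log, scale factor 10,000 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "NormMatrix",
    "QCConfig",
    "QCReport",
    "FormatError",
    "read_counts",
    "write_counts",
    "read_obs_meta",
    "write_obs_meta",
    "validate_obs_meta",
    "qc_filter",
    "normalize_log1p",
]

OBS_META_COLUMNS = ("obs_id", "sample_id", "group")
GROUPS = ("young", "old")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()[:5]
        raise FormatError(f"duplicate {what}: {dup}")


@dataclass
class CountMatrix:
    """Dense observations x genes matrix of non-negative integer counts."""

    obs_ids: pd.Index
    gene_ids: pd.Index
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.obs_ids = pd.Index(self.obs_ids, name="obs_id")
        self.gene_ids = pd.Index(self.gene_ids, name="gene_id")
        self.counts = np.asarray(self.counts)
        _check_unique(self.obs_ids, "obs_ids")
        _check_unique(self.gene_ids, "gene_ids")
        if self.counts.shape != (len(self.obs_ids), len(self.gene_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.obs_ids)} obs x {len(self.gene_ids)} genes"
            )
        if np.any(self.counts < 0):
            i, g = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at obs {self.obs_ids[i]!r}, gene {self.gene_ids[g]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_obs(self, mask_or_ids) -> "CountMatrix":
        if isinstance(mask_or_ids, (list, pd.Index)):
            idx = self.obs_ids.get_indexer(mask_or_ids)
            if np.any(idx < 0):
                missing = pd.Index(mask_or_ids)[idx < 0][:5].tolist()
                raise KeyError(f"unknown obs ids: {missing}")
        else:
            idx = np.flatnonzero(np.asarray(mask_or_ids))
        return CountMatrix(self.obs_ids[idx], self.gene_ids, self.counts[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.obs_ids, columns=self.gene_ids)


@dataclass
class NormMatrix:
    """Log1p library-size-normalized expression, same layout as CountMatrix."""

    obs_ids: pd.Index
    gene_ids: pd.Index
    values: np.ndarray
    scale: float = 1e4

    def __post_init__(self) -> None:
        self.obs_ids = pd.Index(self.obs_ids, name="obs_id")
        self.gene_ids = pd.Index(self.gene_ids, name="gene_id")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_obs(self, mask_or_ids) -> "NormMatrix":
        if isinstance(mask_or_ids, (list, pd.Index)):
            idx = self.obs_ids.get_indexer(mask_or_ids)
            if np.any(idx < 0):
                raise KeyError("unknown obs ids")
        else:
            idx = np.flatnonzero(np.asarray(mask_or_ids))
        return NormMatrix(self.obs_ids[idx], self.gene_ids, self.values[idx], self.scale)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.obs_ids, columns=self.gene_ids)


@dataclass
class QCConfig:
    """Observation-level quality-control thresholds.

    Observations are *removed* when mito fraction strictly exceeds
    ``max_mito_fraction``, when the number of detected genes is strictly
    below ``min_genes``, or (cells only) strictly above ``max_genes``;
    observations exactly at a threshold are retained.  The cell defaults
    (10% mito, 500-6000 genes) and the spot convention (5% mito, 200
    genes, no upper bound) are both expressible here.
    """

    max_mito_fraction: float = 0.10
    min_genes: int = 500
    max_genes: int | None = 6000
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be within [0, 1]")
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        if self.max_genes is not None and self.max_genes <= self.min_genes:
            raise ValueError("max_genes must exceed min_genes")

    @classmethod
    def from_dict(cls, d: dict) -> "QCConfig":
        return cls(**{k: d[k] for k in
                      ("max_mito_fraction", "min_genes", "max_genes", "mito_prefix")
                      if k in d})


@dataclass
class QCReport:
    n_input: int = 0
    n_kept: int = 0
    n_removed_mito: int = 0
    n_removed_min_genes: int = 0
    n_removed_max_genes: int = 0
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_removed_mito": self.n_removed_mito,
            "n_removed_min_genes": self.n_removed_min_genes,
            "n_removed_max_genes": self.n_removed_max_genes,
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# readers / writers


def _read_labels(path: Path, what: str) -> pd.Index:
    if not path.exists():
        raise FormatError(f"missing {what} label file: {path}")
    labels = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str)
    return pd.Index(labels)


def read_counts(path: str | Path, format: str = "dense_tsv") -> CountMatrix:
    """Read a count matrix.

    ``dense_tsv``: header row holds gene ids, first column obs ids.
    ``mtx_triplet``: MatrixMarket file ``<stem>.mtx`` with obs labels in
    ``<dir>/barcodes.tsv`` (rows) and gene labels in ``<dir>/genes.tsv``
    (columns).
    """
    path = Path(path)
    if format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError(f"non-numeric entries in {path}")
        if np.any(arr != np.floor(arr)):
            r, c = np.argwhere(arr != np.floor(arr))[0]
            raise FormatError(
                f"non-integer count at row {r + 2} (obs {df.index[r]!r}) in {path}"
            )
        return CountMatrix(df.index.astype(str), df.columns.astype(str),
                           arr.astype(np.int64))
    if format == "mtx_triplet":
        if not path.exists():
            raise FormatError(f"missing matrix file: {path}")
        mat = scipy.io.mmread(path)
        obs = _read_labels(path.parent / "barcodes.tsv", "barcodes")
        genes = _read_labels(path.parent / "genes.tsv", "genes")
        arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if np.any(arr < 0):
            r, c = np.argwhere(arr < 0)[0]
            raise FormatError(f"negative entry at row {r + 1}, col {c + 1} in {path}")
        if np.any(arr != np.floor(arr)):
            r, c = np.argwhere(arr != np.floor(arr))[0]
            raise FormatError(f"non-integer entry at row {r + 1}, col {c + 1} in {path}")
        return CountMatrix(obs, genes, arr.astype(np.int64))
    raise ValueError(f"unknown format {format!r}")


def write_counts(cm: CountMatrix, path: str | Path, format: str = "dense_tsv") -> None:
    path = Path(path)
    if format == "dense_tsv":
        cm.to_frame().to_csv(path, sep="\t")
    elif format == "mtx_triplet":
        path.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(cm.counts))
        pd.Series(cm.obs_ids).to_csv(path.parent / "barcodes.tsv",
                                     sep="\t", index=False, header=False)
        pd.Series(cm.gene_ids).to_csv(path.parent / "genes.tsv",
                                      sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def validate_obs_meta(meta: pd.DataFrame) -> pd.DataFrame:
    for col in OBS_META_COLUMNS:
        if col not in meta.columns:
            raise FormatError(f"obs metadata missing required column {col!r}")
    _check_unique(meta["obs_id"], "obs_id")
    if meta["group"].isna().any():
        raise FormatError("group column contains missing values")
    bad = set(meta["group"].unique()) - set(GROUPS)
    if bad:
        raise FormatError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
    return meta


def read_obs_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"obs_id": str, "sample_id": str})
    return validate_obs_meta(meta)


def write_obs_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC and normalization


def qc_filter(counts: CountMatrix, cfg: QCConfig) -> tuple[CountMatrix, QCReport]:
    """Remove low-quality observations and flag doublet-like ones.

    An observation fails when its mitochondrial UMI fraction strictly
    exceeds ``cfg.max_mito_fraction``, its detected-gene count is strictly
    below ``cfg.min_genes``, or strictly above ``cfg.max_genes`` (when
    set).  Mito genes are identified case-insensitively by gene-symbol
    prefix; the fraction is computed on raw UMIs.
    """
    report = QCReport(n_input=counts.shape[0])
    totals = counts.counts.sum(axis=1)
    n_detected = (counts.counts > 0).sum(axis=1)

    mito_mask = counts.gene_ids.str.lower().str.startswith(cfg.mito_prefix.lower())
    fail = np.zeros(counts.shape[0], dtype=bool)
    if mito_mask.any():
        with np.errstate(invalid="ignore"):
            mito_frac = np.where(
                totals > 0, counts.counts[:, mito_mask].sum(axis=1) / np.maximum(totals, 1), 0.0
            )
        fail_mito = mito_frac > cfg.max_mito_fraction
    else:
        msg = f"no genes match mito prefix {cfg.mito_prefix!r}; mito rule skipped"
        report.warnings.append(msg)
        warnings.warn(msg)
        fail_mito = np.zeros(counts.shape[0], dtype=bool)
    fail_min = n_detected < cfg.min_genes
    fail_max = (n_detected > cfg.max_genes) if cfg.max_genes is not None else \
        np.zeros(counts.shape[0], dtype=bool)

    report.n_removed_mito = int(fail_mito.sum())
    report.n_removed_min_genes = int(fail_min.sum())
    report.n_removed_max_genes = int(fail_max.sum())
    fail = fail_mito | fail_min | fail_max
    kept = counts.subset_obs(~fail)
    report.n_kept = kept.shape[0]
    return kept, report


def normalize_log1p(counts: CountMatrix, scale: float = 1e4) -> NormMatrix:
    """Library-size normalize to ``scale`` counts per observation, then log1p.

    ``value(i, g) = log(1 + count(i, g) * scale / total(i))``; observations
    with zero total map to an all-zero row.
    """
    totals = counts.counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(totals > 0, counts.counts * (scale / np.maximum(totals, 1.0)), 0.0)
    return NormMatrix(counts.obs_ids, counts.gene_ids, np.log1p(scaled), scale)
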